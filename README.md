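# apesurvey

Analysis pipeline for large interview-based wildlife surveys, built around
the design used to assess orangutan status across Kalimantan: roughly ten
villagers interviewed in each of ~690 villages, drawn as a stratified 40%
sample of a 1,725-village frame.  Interview surveys are cheap and cover
ground that nest-count transects cannot, but they need careful statistical
treatment — respondent reliability screening, an exposure-adjusted encounter
index, principled missing-data handling, models that respect the two-level
design, and survey-weighted extrapolation.  This package implements that
treatment as a tested, reusable library with a synthetic-data generator, so
every stage can be validated end to end without access to interview data.

Intended users: quantitative ecologists and conservation biostatisticians
who run or analyse questionnaire-based species surveys.

## What it computes

**Reliability screening.**  Respondents identify photographs of three focal
primates (orangutan, red langur, Bornean gibbon).  Level 3 = all three
correct, level 2 = orangutan plus one other, level 1 = otherwise.  Villages
whose species-ID records are byte-identical across all respondents (group
interviews or fabrication) are demoted wholesale to level 1.  Only levels
\>1 enter orangutan analyses.

**Relative Encounter (RE) index.**  For each respondent,

```
RE = reported presence / (FT × TrD)
```

where *FT* is the scaled annual forest-trip frequency
(>4/wk → 260, 2–4/wk → 156, 1–2/wk → 78, 1–2/mo → 18, 1–2/yr → 2,
<1/yr → 1, 0 → 0), *TrD* the trip-duration multiplier (0 nights → 1.0,
1–4 → 1.1, >4 → 1.25), and a respondent who saw an orangutan without
entering the forest gets potential 1.  Village RE is the mean over reliable
respondents, classed 1–4 (class 1 = exactly zero; classes 2–4 = tertiles of
the positive villages).

**Missing data.**  Three datasets: (i) complete cases; (ii) after inferring
logically forced values (e.g. "saw none last year" ⇒ count 0); (iii) after
additionally imputing the remainder with ten-fold model-based imputation
(bootstrap the complete rows, fit per-variable prediction models, predict
every missing cell; final value = mean of ten predictions, with a per-cell
variance).

**Two-level models.**  Random-intercept GLMMs (villagers nested in
villages) for binary outcomes, fit by maximum likelihood with adaptive
Gauss–Hermite quadrature; Gaussian outcomes use the linear mixed model.
Flat GLM baselines and deviance comparisons quantify what ignoring the
design would cost.

**Extrapolation.**  Stratum weights (frame/sample villages per threat
stratum; the fully-sampled high-threat stratum gets weight 1), demographic
sampling ratios against census counts, and a finite-population correction
(1 − n/N) on the variances, with normal or bootstrap CIs.

**QC & sensitivity.**  Temporal-recall conflict rates over nested
timeframes, location-precision summaries, within/among-village ANOVA,
selection-method comparisons, five 80% subsample refits, and alternative
covariate sets.

## Worked example

```python
from apesurvey import (SimulationConfig, simulate_survey, ReliabilityScorer,
                       EncounterIndex, ModelSpec, fit_glmm, fit_flat)

cfg = SimulationConfig(n_villages=1725, seed=1, missing_rate=0.0)
villagers, villages, truth = simulate_survey(cfg)   # 690 villages, 6,900 rows

villagers = ReliabilityScorer().fit_transform(villagers)
enc = EncounterIndex()
villagers = enc.fit_transform(villagers)            # adds FT, TrD, presence, RE
village_re = enc.village_table(villagers)           # mean RE + class per village

villagers["age_z"] = (villagers["age"].astype(float) - 40) / 13
spec = ModelSpec(outcome="presence", family="binomial", fixed_covariates=("age_z",))
reliable = villagers[villagers["reliability_level"] > 1]
ml, flat = fit_glmm(reliable, spec), fit_flat(reliable, spec)
```

Output from this exact run:

```
reliability shares: {3: 0.705, 2: 0.132, 1: 0.163}
village RE class counts: {1: 40, 2: 197, 3: 196, 4: 196}
GLMM: beta0=-0.518 (se 0.048), age_z=0.009 (se 0.031), sigma_v=0.919
deviance multilevel 7408.8 vs flat 7731.6
```

The reliability shares land on the configured 0.701/0.132/0.167 mixture;
the 40 zero-RE villages take class 1 and the positive villages split into
tertiles; the village random-intercept s.d. of 0.92 recovers the generating
value of 1.0 within sampling error, and the ~320-point deviance gap shows
what a design-ignorant logistic regression would miss on clustered data.

A CLI wraps the same stages:

```
apesurvey all --seed 1 --out results/
apesurvey simulate --seed 1 --out results/
```

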
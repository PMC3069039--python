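# Methods

This note records the statistical models the package implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot establish.

## Survey design being modelled

A two-level interview survey: a sampling frame of 1,725 villages within the
species' suspected range, stratified by threat of land-use change
(high/medium/low).  Every high-threat village is sampled and a random
subset of the others, giving a ~40% sample (~690 villages); ten villagers
are interviewed per village.  Analyses treat villagers as nested in
villages, because respondents from the same village share exposure,
information and interviewer.

## Synthetic-data generator

The generator (`apesurvey.simulate`) emulates the statistical structure the
downstream stages assume.  Defaults are the study conditions where those
are known, and a documented field-realistic choice where they are not.

| Parameter | Default | Source / rationale |
|---|---|---|
| `n_villages` (frame) | 1725 | study frame size |
| `sampling_fraction` | 0.40 | study design |
| `respondents_per_village` | 10 | study design |
| `male_fraction` | 0.888 | respondent share in the study |
| `reliability_mix` (levels 3/2/1) | 0.701 / 0.132 / 0.167 | study shares |
| `fraud_village_rate` | 0.086 | ≈598 identical-block interviews / 6,972 ≈ 60 villages of ~690 |
| `conflict_rate` | 0.02 | "less than 2%" conflicting recall regime |
| `missing_rate` (per cell) | 0.05 | yields ≈80% of rows complete on the ~5 analysis fields ((1−0.05)⁵ ≈ 0.77), matching the share the rule-inferred dataset retains |
| `stratum_proportions` | 0.15 / 0.45 / 0.40 | not reported; high stratum must fit inside the 40% sample since it is fully taken |
| `village_random_sd` | 1.0 | moderate clustering on the logit scale (intra-class correlation ≈ 0.23) |
| `base_presence_logit` | −1.0 | ≈27% marginal sighting propensity |
| trip-frequency cell probabilities | (.05,.10,.15,.20,.15,.10,.25) | instrument defines cells, not frequencies; chosen to cover all cells with a realistic mode at monthly trips |
| nights-per-trip probabilities | (.60,.30,.10) | day trips dominate |
| location-precision probabilities | (.30,.30,.26,.09,.05) | 86% of ratings in 1–3 |
| selection-method probabilities | (.64,.18,.18) | random / suggested / volunteered shares |
| ethnicity / religion shares | (.663,.168,.165,.004) / (.48,.48,.04) | respondent composition |

Mechanics worth knowing:

* **Named substreams.**  Every field draws from its own RNG substream
  derived from (seed, field name), so adding a field never perturbs earlier
  draws and a seed fully determines the output bytes.
* **Reliability mixture is marginal.**  Fraud villages (identical
  species-ID blocks) are demoted to level 1 by the screening rule, so
  non-fraud respondents draw levels from rescaled probabilities such that
  the *marginal* level distribution equals `reliability_mix`.
  `fraud_village_rate` may not exceed the level-1 share.
* **Recall conflicts** are injected by flipping a shorter-timeframe answer
  positive against a longer-timeframe negative ("seen last week" yes,
  "seen last year" no) in `conflict_rate` of ever-seen respondents.
* **Demographics are independent.**  Joint distributions of sex, ethnicity
  and religion are not reported anywhere, so the generator samples them
  independently.

What passing tests on this data do *not* show: robustness to non-MCAR
missingness, to spatially structured presence, to interviewer effects
beyond the identical-block construct, or to misreporting driven by social
desirability (relevant to killing/hunting questions).  Those are real-data
phenomena outside the generator's scope.

## Relative Encounter index

`RE = presence / (FT × TrD)` with the scalings in the README.  Decisions:

* **Nights boundary.**  The duration rule as stated overlaps at four
  nights ("1–4 nights" ×1.1 and "4 nights" ×1.25); the package reads the
  second rule as ">4 nights", consistent with the three-cell vocabulary
  {0, 1–4, >4}.
* **Presence without exposure.**  A respondent who reports presence but no
  forest trips gets potential 1 rather than an undefined 0-division; a
  respondent with neither presence nor exposure has RE 0.
* **Classing.**  "Quartiles of zero, low, medium, high" is implemented as:
  class 1 = exactly zero, classes 2–4 = tertiles of the strictly positive
  village means (boundary values to the lower class).  A plain quartile
  scheme over all values is available via `EncounterIndex(scheme="quartile")`.
  Rationale: zero-RE villages can dominate the distribution, in which case
  plain quartiles would leave the upper classes empty while observed
  positive scores as low as 0.043 belong to the top class.
* **Numerator.**  The binary reported-presence indicator is used, not the
  sighting count; the count variant is deliberately not enabled.
* Missing presence propagates to missing RE; filling it is the missing-data
  stage's job, never this module's.

## Reliability screening

Correctness of a photo answer is judged against a configurable answer key
with accepted vernacular synonyms per species (which local names count was
a field decision; the default key mirrors the generator's pools).  A
missing answer counts as incorrect — conservative, in line with demoting
identical blocks.  The false-positive control photo (douc langur) is
carried in the schema but never scored, since misidentification cannot be
separated from "absent here".  Level 2 is "orangutan plus at least one
other"; the exactly-one reading is indistinguishable because all-three
correct is classified as level 3 first.

## Missing data

Dataset (ii) — rule inference then complete-case filtering — is the default
input for modelling.  Inference rules encode only logically forced
implications (timeframe nesting, count/indicator consistency) and run to a
fixpoint, with every change logged and contradictory rule firings a hard
error.

Ten-fold imputation follows the bootstrap-predict scheme: each of ten
rounds resamples the rows complete in (covariates + target) with
replacement, fits binary → logistic, categorical → multinomial,
continuous → linear models, and predicts all missing cells.  Final values
are the mean of the ten predictions; binary cells threshold the mean
probability at 0.5 (ties to "no"), categorical cells take the majority.

Two local decisions matter for inference downstream:

* **Covariates include the sighting answers.**  Rule inference resolves
  every cell that sibling answers force, so the cells reaching the imputer
  are a selected subset (e.g. `ever_seen` is only still missing where
  `seen_last_year` is "no").  A model blind to those answers overestimates
  prevalence; the default covariate set therefore includes them (a variable
  never predicts itself).  The list is configurable.
* **Prevalence uses mean probabilities.**  Majority-vote labels are biased
  toward the majority class, so `ImputedDataset.binary_prevalence` combines
  observed labels with the retained per-cell mean predicted probabilities.
  The thresholded labels exist for categorical semantics, not estimation.

Per-cell provenance (observed / rule_inferred / imputed) partitions the
table exactly; observed cells are never altered.  Full multiple-imputation
combining rules across completed datasets are out of scope — the scheme
collapses to the mean with a per-cell variance.

## Two-level models

Binary outcomes: `logit P(y_ij=1|u_j) = x_ij'β + σ_v u_j`, `u_j ~ N(0,1)`.
The marginal likelihood integrates `u_j` per village by **adaptive**
Gauss–Hermite quadrature: per village the integrand is re-centred at its
mode (Newton, vectorised over villages) and re-scaled by its curvature
before the Hermite rule, keeping 15 nodes (default) accurate for villages
of any size.  Optimisation is L-BFGS-B over (β, σ_v) with σ_v ≥ 0, started
from the flat GLM, followed by a short Newton polish on numerical
derivatives so the optimum is pinned well below the stopping tolerance
(this is what makes estimates row-order invariant at the 1e-8 level).
Standard errors come from the numerically evaluated observed information;
a singular information matrix falls back to the pseudo-inverse with a note.
Penalised quasi-likelihood is deliberately not re-implemented: quadrature
is reproducible and testable against closed forms and an independent
reference implementation.

Gaussian outcomes use statsmodels `MixedLM` by ML (not REML, so deviances
are comparable across fixed-effect specs), refined on the exact
closed-form marginal likelihood (GLS-profiled β, Woodbury identities per
group) to pin the optimum.

Deviance is −2·logL throughout; for binary data this equals the usual GLM
deviance since the saturated log-likelihood is zero.  The flat-vs-multilevel
comparison notes that the null σ_v = 0 sits on the boundary and reports the
50:50 χ²(0)/χ²(1) mixture p-value.  Only village intercepts are random:
"villagers within villages" as a second random level is inestimable with
one binary observation per villager, so the villager level is the residual.
With fewer than two villages the flat fit is returned with a warning.

Covariate sets for the primary models are configuration, not doctrine: the
shipped default (an age covariate over the reliable subset) is a
demonstration set, and the sensitivity harness exists precisely to vary it.

## Extrapolation

Stratum weight = frame villages / sampled villages; the fully sampled
high-threat stratum gets weight 1.  Villager-level weights default to
equal — the sample is treated as representative of the sub-population with
propensity to encounter the species, not of the census population — while
demographic ratios (respondents per census head, per category) quantify
the sample's non-representativeness.  The FPC is the simple `1 − n/N`
variance multiplier (the `(N−n)/(N−1)` form differs by <0.1% at study
scale and is available via `form="classic"`).  CIs are normal
approximations by default with a seeded percentile bootstrap for small
strata.

Worst-case precision bounds: a proportion from n respondents has s.d. at
most √(0.25/n) (0.00599 at n = 6,972); the extrapolated presence count has
s.d. at most √(n/4)·(1725/687) ≈ 104.8.  The analogous *sample*-count
bound √(n/4) evaluates to 41.7, not the reported ≤40; whether an FPC was
applied to that figure is unstated, so both computations are exposed
(`max_count_sd` with and without expansion) and the discrepancy is left
unresolved rather than forced.

## QC and sensitivity

A recall conflict is any shorter-window positive against a longer-window
negative in the nested chain week ⊂ month ⊂ year ⊂ ever; the rate is
computed over respondents who ever saw the species.  Variance decomposition
uses linear-model one-way ANOVA even for binary responses (documented
approximation); a zero within-village mean square reports an infinite F
with a flag.  The selection-method comparison flags a difference as
substantive only below p < 0.01 *and* above a 2-percentage-point absolute
gap — thresholds in config, since none are stated.  Stability harnesses
refit the final specs on five seeded 80% simple random subsamples and on
alternative covariate sets, reporting sign and significance agreement;
failed refits are recorded, not fatal.  Interviews recorded as shorter than
one minute are counted and reported, with no fraud adjudication attempted.

## Problem sizes used in the checks

The heavy end-to-end checks run at the study's design scale — 690 villages
× 10 respondents for mixed-model recovery (20 replicates) — and at 120
villages × 10 for the imputation calibration replicates, a size at which
the Monte-Carlo error of the calibration statistic is already far below
the tolerances being checked.

## Known limitations

* MCAR is the only missingness mechanism generated or claimed.
* The imputation model families (logistic/multinomial/linear) are a
  documented choice; the original analysis software's families are not
  recorded anywhere.
* RE is relative: no conversion to absolute density is attempted, and the
  quartile/tertile classing is only as comparable across surveys as the
  underlying exposure distributions.
* No spatial structure: village placement, spatial correlation of presence
  and GIS aggregation are out of scope.
* The identical-block rule detects only *perfect* duplication; partial
  copying or coached answers pass through it.
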
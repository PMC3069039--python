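"""Data-quality checks and sensitivity harness.

Covers the consistency checks run on the questionnaire responses —
contradictions between nested recall timeframes, location-precision
ratings, identical-answer village blocks, implausibly short interviews,
within- vs among-village variance decomposition, comparison of respondent
selection methods — and the model-stability harness: refitting the final
models on random 80% subsamples and on alternative covariate sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import ModelFit, ModelSpec, fit_glmm
from .reliability import flag_identical_blocks

__all__ = [
    "ConsistencyReport",
    "StabilityReport",
    "temporal_consistency",
    "variance_decomposition",
    "selection_method_comparison",
    "subsample_stability",
    "alternative_models",
    "consistency_report",
]

#: nested recall windows, shortest first; a positive in a shorter window
#: contradicting a negative in any longer window is a recall conflict
TIMEFRAME_FIELDS = ("seen_last_week", "seen_last_month", "seen_last_year", "ever_seen")


@dataclass
class ConsistencyReport:
    conflict_rate: float  # among respondents who ever saw an orangutan
    n_conflicting: int
    n_ever_seen: int
    precision_share_1to3: float
    n_rated: int
    identical_block_villages: int
    short_interviews: int  # recorded duration under one minute
    anova: dict[str, dict] = field(default_factory=dict)


def temporal_consistency(villagers: pd.DataFrame) -> tuple[float, int, int]:
    """Rate of contradictory timeframe answers among ever-seen positives.

    A respondent conflicts iff some shorter-window answer is ``yes`` while a
    longer-window answer is ``no`` (week within month within year within
    ever).  Missing answers never create a conflict.
    """
    present = [f for f in TIMEFRAME_FIELDS if f in villagers.columns]
    ever = villagers["ever_seen"] == "yes"
    conflict = pd.Series(False, index=villagers.index)
    for i, shorter in enumerate(present):
        for longer in present[i + 1:]:
            conflict |= (villagers[shorter] == "yes") & (villagers[longer] == "no")
    n_ever = int(ever.sum())
    n_conf = int((conflict & ever).sum())
    rate = n_conf / n_ever if n_ever else 0.0
    return rate, n_conf, n_ever


def variance_decomposition(villagers: pd.DataFrame, question: str) -> dict:
    """One-way ANOVA of a response on village: between/within mean squares
    and F.  Binary yes/no responses are coded 0/1 (linear-model ANOVA as an
    approximation).  Degenerate grouping (fewer than two villages with two
    respondents) is an error; a zero within-village mean square yields an
    infinite F, reported capped and flagged.
    """
    data = villagers[["village_id", question]].dropna()
    y = data[question]
    if y.dtype == object:
        y = y.map({"yes": 1.0, "no": 0.0})
    data = pd.DataFrame({"village_id": data["village_id"], "y": pd.to_numeric(y)}).dropna()
    sizes = data.groupby("village_id").size()
    if (sizes >= 2).sum() < 2:
        raise ValueError("need >= 2 villages with >= 2 respondents for variance decomposition")
    grand = data["y"].mean()
    grp = data.groupby("village_id")["y"]
    n_j = grp.size().to_numpy(float)
    mean_j = grp.mean().to_numpy()
    ss_between = float((n_j * (mean_j - grand) ** 2).sum())
    ss_within = float(((data["y"] - grp.transform("mean")) ** 2).sum())
    k = len(n_j)
    n = len(data)
    ms_between = ss_between / (k - 1)
    df_within = n - k
    ms_within = ss_within / df_within if df_within > 0 else np.nan
    capped = False
    if ms_within == 0:
        f_stat = np.inf
        capped = True
        p = 0.0
    else:
        f_stat = ms_between / ms_within
        p = float(stats.f.sf(f_stat, k - 1, df_within))
    return {
        "question": question,
        "ms_between": ms_between,
        "ms_within": ms_within,
        "F": float(f_stat),
        "df": (k - 1, df_within),
        "p_value": p,
        "within_ms_zero": capped,
    }


def selection_method_comparison(
    villagers: pd.DataFrame,
    outcomes: tuple[str, ...] = ("ever_seen", "seen_last_year"),
    p_threshold: float = 0.01,
    min_abs_diff: float = 0.02,
) -> pd.DataFrame:
    """Compare outcome distributions across respondent selection methods
    (random / suggested / volunteered).

    Binary outcomes get a chi-square test of independence; numeric outcomes
    a one-way ANOVA.  A difference is flagged *substantive* only when the
    p-value is below ``p_threshold`` and (for binary outcomes) the largest
    between-group gap in the positive share exceeds ``min_abs_diff``.
    Absent selection classes reduce the comparison with a warning note.
    """
    rows = []
    present_classes = [c for c in ("random", "suggested", "volunteered")
                       if (villagers["selection_method"] == c).any()]
    note = None
    if len(present_classes) < 3:
        note = f"selection classes present: {present_classes}"
    for outcome in outcomes:
        data = villagers[["selection_method", outcome]].dropna()
        data = data[data["selection_method"].isin(present_classes)]
        if len(present_classes) < 2 or data.empty:
            rows.append({"outcome": outcome, "test": "none", "p_value": np.nan,
                         "max_abs_diff": np.nan, "flag": False, "note": note or "insufficient classes"})
            continue
        y = data[outcome]
        if y.dtype == object:
            tab = pd.crosstab(data["selection_method"], y)
            if tab.shape[1] < 2:
                p = 1.0
                max_diff = 0.0
            else:
                p = float(stats.chi2_contingency(tab)[1])
                share = tab.div(tab.sum(axis=1), axis=0)
                pos = share["yes"] if "yes" in share.columns else share.iloc[:, 0]
                max_diff = float(pos.max() - pos.min())
            test = "chi2"
        else:
            groups = [g.to_numpy(float) for _, g in data.groupby("selection_method")[outcome]]
            p = float(stats.f_oneway(*groups)[1]) if len(groups) > 1 else 1.0
            means = data.groupby("selection_method")[outcome].mean()
            max_diff = float(means.max() - means.min())
            test = "anova"
        flag = bool(p < p_threshold and max_diff > min_abs_diff)
        rows.append({"outcome": outcome, "test": test, "p_value": p,
                     "max_abs_diff": max_diff, "flag": flag, "note": note})
    return pd.DataFrame(rows)


@dataclass
class StabilityReport:
    """Per-run fits plus cross-run agreement summaries."""

    fits: list[dict]
    sign_agreement: dict[str, bool]
    significance_agreement: dict[str, bool]
    failures: list[dict] = field(default_factory=list)


def _agreement(fits: list[ModelFit]) -> tuple[dict, dict]:
    if not fits:
        return {}, {}
    terms = fits[0].beta.keys()
    sign_ok, sig_ok = {}, {}
    for t in terms:
        if not all(t in f.beta for f in fits):
            continue
        signs = {np.sign(f.beta[t]) for f in fits}
        sign_ok[t] = len(signs) == 1
        sigs = {abs(f.beta[t]) > 1.96 * f.se[t] if f.se[t] > 0 else False for f in fits}
        sig_ok[t] = len(sigs) == 1
    return sign_ok, sig_ok


def subsample_stability(
    df: pd.DataFrame,
    spec: ModelSpec,
    k: int = 5,
    frac: float = 0.8,
    seed: int = 0,
    **fit_kwargs,
) -> StabilityReport:
    """Refit ``spec`` on ``k`` seeded simple random subsamples of villagers
    (default five 80% subsamples) and summarise sign / significance
    agreement of every fixed effect across the refits."""
    rng = np.random.default_rng(seed)
    fits, records, failures = [], [], []
    for i in range(k):
        idx = rng.choice(df.index, size=int(round(frac * len(df))), replace=False)
        sub = df.loc[np.sort(idx)]
        try:
            f = fit_glmm(sub, spec, **fit_kwargs)
            fits.append(f)
            records.append({"run": i, "beta": f.beta, "se": f.se,
                            "sigma_v": f.sigma_v, "converged": f.converged})
        except Exception as exc:  # a failed subsample fit is recorded, not fatal
            failures.append({"run": i, "error": str(exc)})
    sign_ok, sig_ok = _agreement(fits)
    return StabilityReport(fits=records, sign_agreement=sign_ok,
                           significance_agreement=sig_ok, failures=failures)


def alternative_models(
    df: pd.DataFrame,
    base_spec: ModelSpec,
    covariate_pool: tuple[tuple[str, ...], ...],
    **fit_kwargs,
) -> StabilityReport:
    """Fit the base spec plus alternative covariate sets and summarise the
    stability of the effects shared across specifications."""
    if not covariate_pool:
        raise ValueError("covariate pool must be non-empty")
    specs = [base_spec] + [
        ModelSpec(outcome=base_spec.outcome, family=base_spec.family,
                  fixed_covariates=tuple(covs), grouping=base_spec.grouping)
        for covs in covariate_pool
        if tuple(covs) != tuple(base_spec.fixed_covariates)
    ]
    fits, records, failures = [], [], []
    for i, spec in enumerate(specs):
        try:
            f = fit_glmm(df, spec, **fit_kwargs)
            fits.append(f)
            records.append({"run": i, "covariates": list(spec.fixed_covariates),
                            "beta": f.beta, "se": f.se, "sigma_v": f.sigma_v})
        except Exception as exc:
            failures.append({"run": i, "covariates": list(spec.fixed_covariates),
                             "error": str(exc)})
    sign_ok, sig_ok = _agreement(fits)
    return StabilityReport(fits=records, sign_agreement=sign_ok,
                           significance_agreement=sig_ok, failures=failures)


def consistency_report(
    villagers: pd.DataFrame,
    anova_questions: tuple[str, ...] = ("seen_last_year", "village_ever_killed"),
) -> ConsistencyReport:
    """Assemble the full data-quality report for a villager table."""
    rate, n_conf, n_ever = temporal_consistency(villagers)
    saw = villagers["ever_seen"] == "yes"
    rated = villagers.loc[saw, "location_precision"].dropna()
    share = float((rated <= 3).mean()) if len(rated) else float("nan")
    n_blocks = len(flag_identical_blocks(villagers))
    short = 0
    if {"interview_start", "interview_end"} <= set(villagers.columns):
        start = pd.to_datetime(villagers["interview_start"], errors="coerce")
        end = pd.to_datetime(villagers["interview_end"], errors="coerce")
        dur = (end - start).dt.total_seconds()
        short = int((dur < 60).sum())
    anova = {}
    for q in anova_questions:
        if q in villagers.columns:
            try:
                anova[q] = variance_decomposition(villagers, q)
            except ValueError:
                continue
    return ConsistencyReport(
        conflict_rate=rate,
        n_conflicting=n_conf,
        n_ever_seen=n_ever,
        precision_share_1to3=share,
        n_rated=int(len(rated)),
        identical_block_villages=n_blocks,
        short_interviews=short,
        anova=anova,
    )
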
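"""Data-quality checks and sensitivity harness."""

import math

import numpy as np
import pandas as pd
import pytest

from apesurvey.encounter import EncounterIndex
from apesurvey.glmm import ModelSpec
from apesurvey.qc import (
    alternative_models,
    consistency_report,
    selection_method_comparison,
    subsample_stability,
    temporal_consistency,
    variance_decomposition,
)
from apesurvey.simulate import SimulationConfig, simulate_survey


def test_week_positive_year_negative_is_conflict():
    df = pd.DataFrame(
        {
            "ever_seen": ["yes", "yes"],
            "seen_last_year": ["no", "yes"],
            "seen_last_month": ["no", "no"],
            "seen_last_week": ["yes", "no"],
        }
    )
    rate, n_conf, n_ever = temporal_consistency(df)
    assert (n_conf, n_ever) == (1, 2)
    assert rate == 0.5


def test_all_consistent_table_rate_zero(tiny_villagers):
    rate, n_conf, _ = temporal_consistency(tiny_villagers)
    assert rate == 0.0 and n_conf == 0


def test_missing_answers_never_conflict():
    df = pd.DataFrame(
        {"ever_seen": ["yes"], "seen_last_year": [None], "seen_last_week": ["yes"]}
    )
    rate, n_conf, _ = temporal_consistency(df)
    assert n_conf == 0


def test_generated_conflict_rate_calibrated(survey_factory):
    villagers, _, truth = survey_factory(seed=31, n_villages=1725, missing_rate=0.0)
    rate, n_conf, n_ever = temporal_consistency(villagers)
    se = math.sqrt(0.02 * 0.98 / n_ever)
    assert abs(rate - 0.02) < 3 * se
    assert rate < 0.05  # the study's "less than 2%" regime, with head room


def test_variance_decomposition_clustered_vs_flat():
    rng = np.random.default_rng(2)
    clustered = pd.DataFrame(
        {
            "village_id": np.repeat(list("ABCD"), 5),
            "resp": np.repeat([0.0, 1.0, 0.0, 1.0], 5),  # identical within
        }
    )
    out = variance_decomposition(clustered, "resp")
    assert out["within_ms_zero"] and np.isinf(out["F"])
    # fully random responses: F near 1 in expectation
    fs = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "village_id": np.repeat(np.arange(30), 10),
                "resp": rng.random(300),
            }
        )
        fs.append(variance_decomposition(df, "resp")["F"])
    assert 0.7 < np.mean(fs) < 1.4


def test_variance_decomposition_binary_and_errors(tiny_villagers):
    out = variance_decomposition(tiny_villagers, "ever_seen")
    assert out["ms_within"] >= 0
    single = tiny_villagers[tiny_villagers["village_id"] == "A"]
    with pytest.raises(ValueError):
        variance_decomposition(single, "ever_seen")


def test_selection_comparison_null_rarely_flags(survey_factory):
    """The generator draws selection method independently of responses, so
    substantive-difference flags should be rare."""
    clean = 0
    for seed in range(10):
        villagers, _, _ = survey_factory(seed=100 + seed, n_villages=400, missing_rate=0.0)
        out = selection_method_comparison(villagers)
        clean += not out["flag"].any()
    assert clean >= 8


def test_selection_comparison_detects_injected_effect(survey_factory):
    villagers, _, _ = survey_factory(seed=41, n_villages=400, missing_rate=0.0)
    rigged = villagers.copy()
    vol = rigged["selection_method"] == "volunteered"
    rigged.loc[vol, "ever_seen"] = "yes"  # strong voluntary-response bias
    out = selection_method_comparison(rigged)
    assert out.loc[out["outcome"] == "ever_seen", "flag"].item()


def test_selection_comparison_single_class():
    df = pd.DataFrame({"selection_method": ["random"] * 4, "ever_seen": ["yes", "no"] * 2})
    out = selection_method_comparison(df, outcomes=("ever_seen",))
    assert not out["flag"].any()
    assert out["note"].notna().all()


def _modelled_survey(seed, n_villages=200, effect=0.8):
    cfg = SimulationConfig(
        n_villages=n_villages, seed=seed, missing_rate=0.0, conflict_rate=0.0,
        covariate_effects={"age_z": effect},
    )
    v, _, _ = simulate_survey(cfg)
    v = EncounterIndex().fit_transform(v)
    v["age_z"] = (v["age"].astype(float) - 40.0) / 13.0
    v["noise"] = np.random.default_rng(seed).normal(size=len(v))
    return v


def test_subsample_stability_strong_effect():
    v = _modelled_survey(seed=3)
    spec = ModelSpec(outcome="presence", family="binomial", fixed_covariates=("age_z",))
    rep = subsample_stability(v, spec, k=5, frac=0.8, seed=1)
    assert len(rep.fits) == 5 and not rep.failures
    assert rep.sign_agreement["age_z"]
    assert rep.significance_agreement["age_z"]


def test_subsample_stability_k_zero_empty():
    v = _modelled_survey(seed=3, n_villages=50)
    spec = ModelSpec(outcome="presence", family="binomial", fixed_covariates=("age_z",))
    rep = subsample_stability(v, spec, k=0)
    assert rep.fits == [] and rep.sign_agreement == {}


def test_alternative_models_orthogonal_covariate_stable():
    v = _modelled_survey(seed=9)
    base = ModelSpec(outcome="presence", family="binomial", fixed_covariates=("age_z",))
    rep = alternative_models(v, base, (("age_z",), ("age_z", "noise")))
    assert len(rep.fits) == 2
    b0, b1 = rep.fits[0]["beta"]["age_z"], rep.fits[1]["beta"]["age_z"]
    assert b0 == pytest.approx(b1, abs=0.05)  # independent covariate barely moves it
    assert rep.sign_agreement["age_z"]
    with pytest.raises(ValueError):
        alternative_models(v, base, ())


def test_consistency_report_assembles(survey_factory):
    villagers, _, truth = survey_factory(seed=19, n_villages=300, missing_rate=0.0)
    rep = consistency_report(villagers)
    assert 0 <= rep.conflict_rate <= 1
    assert 0 <= rep.precision_share_1to3 <= 1
    assert rep.identical_block_villages >= len(truth.fraud_villages)
    assert rep.short_interviews > 0  # generator plants a few rushed interviews
    assert "seen_last_year" in rep.anova
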
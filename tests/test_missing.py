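"""Missing data: complete cases, rule inference, bootstrap imputation."""

import math

import numpy as np
import pandas as pd
import pytest

from apesurvey.missing import (
    DEFAULT_RULES,
    InferenceRule,
    RuleConflictError,
    build_datasets,
    complete_cases,
    impute_tenfold,
    infer_obvious,
)


def test_complete_cases_counts(tiny_villagers):
    df = tiny_villagers.copy()
    df.loc[0, "sex"] = None
    df.loc[3, "trips_category"] = None
    out = complete_cases(df, ("sex", "trips_category"))
    assert len(out) == 4
    # no missing anywhere -> identity
    assert len(complete_cases(tiny_villagers, ("sex",))) == len(tiny_villagers)
    # everything missing -> empty
    allmiss = df.assign(sex=None)
    assert complete_cases(allmiss, ("sex",)).empty
    with pytest.raises(ValueError):
        complete_cases(df, ())


def test_infer_zero_count_from_no_sighting():
    df = pd.DataFrame({"seen_last_year": ["no", "yes"], "n_seen_last_year": [np.nan, np.nan]})
    out, log = infer_obvious(df)
    assert out.loc[0, "n_seen_last_year"] == 0
    assert np.isnan(out.loc[1, "n_seen_last_year"])  # positive sighting: count unknown
    assert log == [{"row": 0, "field": "n_seen_last_year",
                    "rule_id": "no_sighting_zero_count", "value": 0.0}]


def test_inference_chains_to_fixpoint():
    """never-seen forces not-seen-last-year, which forces a zero count."""
    df = pd.DataFrame(
        {"ever_seen": ["no"], "seen_last_year": [None], "n_seen_last_year": [np.nan]}
    )
    out, log = infer_obvious(df)
    assert out.loc[0, "seen_last_year"] == "no"
    assert out.loc[0, "n_seen_last_year"] == 0
    assert {e["rule_id"] for e in log} >= {"never_seen_not_last_year", "no_sighting_zero_count"}


def test_unrelated_fields_left_missing(tiny_villagers):
    df = tiny_villagers.assign(village_age=np.nan)  # nothing can force this
    out, _ = infer_obvious(df)
    assert out["village_age"].isna().all()


def test_observed_cells_never_altered(tiny_villagers):
    out, _ = infer_obvious(tiny_villagers)
    pd.testing.assert_frame_equal(out, tiny_villagers)


def test_contradictory_rules_raise():
    rules = DEFAULT_RULES + (
        InferenceRule("bogus", "seen_last_year", "no", "n_seen_last_year", 9.0),
    )
    df = pd.DataFrame({"seen_last_year": ["no"], "n_seen_last_year": [np.nan]})
    with pytest.raises(RuleConflictError, match="bogus"):
        infer_obvious(df, rules)


def test_impute_no_missing_is_identity(tiny_villagers):
    complete = tiny_villagers.assign(
        location_precision=tiny_villagers["location_precision"].fillna(4.0)
    )
    res = impute_tenfold(complete, seed=4)
    pd.testing.assert_frame_equal(res.values, complete)
    assert res.imputation_variance.empty
    assert (res.provenance == "observed").all().all()


def test_impute_deterministic_under_seed(survey_factory):
    villagers, _, _ = survey_factory(seed=17, n_villages=60, missing_rate=0.1)
    a = impute_tenfold(villagers, seed=5)
    b = impute_tenfold(villagers, seed=5)
    pd.testing.assert_frame_equal(a.values, b.values)
    c = impute_tenfold(villagers, seed=6)
    assert not a.values.equals(c.values)


def test_provenance_partition_exact(survey_factory):
    villagers, _, _ = survey_factory(seed=17, n_villages=60, missing_rate=0.1)
    ds = build_datasets(villagers, seed=2)
    prov = ds["iii"].provenance
    allowed = {"observed", "rule_inferred", "imputed", "missing"}
    assert set(np.unique(prov.to_numpy())) <= allowed
    # observed cells never altered
    obs_mask = villagers.notna()
    vals = ds["iii"].values
    for col in ("sex", "trips_category", "ever_seen"):
        same = vals.loc[obs_mask[col], col] == villagers.loc[obs_mask[col], col]
        assert same.all()
    # every originally-missing analysis cell is rule_inferred or imputed
    for col in ("seen_last_year", "n_seen_last_year"):
        tags = prov.loc[villagers[col].isna(), col]
        assert set(tags) <= {"rule_inferred", "imputed"}
    assert (ds["iii"].imputation_variance["variance"] >= 0).all()


def test_imputed_binary_prevalence_unbiased(survey_factory):
    """20% MCAR masking of a binary field: imputed prevalence tracks the
    complete-data prevalence within 3 binomial s.e. of the masked count."""
    villagers, _, _ = survey_factory(seed=23, n_villages=300, missing_rate=0.0,
                                     conflict_rate=0.0)
    truth_prev = (villagers["ever_seen"] == "yes").mean()
    masked = villagers.copy()
    rng = np.random.default_rng(8)
    mask = rng.random(len(masked)) < 0.2
    masked.loc[mask, "ever_seen"] = None
    res = impute_tenfold(masked, variables=("ever_seen",), seed=8)
    est_prev = res.binary_prevalence("ever_seen")
    # imputation error only affects the masked share of the rows
    se_masked_rows = math.sqrt(truth_prev * (1 - truth_prev) * mask.sum()) / len(masked)
    assert abs(est_prev - truth_prev) < 3 * se_masked_rows


def test_variable_with_no_observed_rows_errors(tiny_villagers):
    df = tiny_villagers.assign(mystery=np.nan)
    with pytest.raises(ValueError):
        impute_tenfold(df, variables=("mystery",), seed=1)


def test_build_datasets_shapes(survey_factory):
    villagers, _, _ = survey_factory(seed=17, n_villages=60, missing_rate=0.1)
    ds = build_datasets(villagers, seed=3)
    assert len(ds["i"]) <= len(ds["ii"]) <= len(villagers)
    assert len(ds["iii"].values) == len(villagers)
    assert ds["inference_log"]


def test_rules_round_trip_from_config(tmp_path):
    import yaml

    from apesurvey.missing import rules_from_config

    path = tmp_path / "rules.yaml"
    path.write_text(yaml.safe_dump([
        {"rule_id": "r1", "if_field": "seen_last_year", "if_value": "no",
         "then_field": "n_seen_last_year", "then_value": 0.0},
    ]))
    rules = rules_from_config(path)
    df = pd.DataFrame({"seen_last_year": ["no"], "n_seen_last_year": [np.nan]})
    out, log = infer_obvious(df, rules)
    assert out.loc[0, "n_seen_last_year"] == 0.0
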
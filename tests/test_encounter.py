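"""Relative Encounter metric: scalings, potential, RE, village means, classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apesurvey.encounter import (
    FT_SCALE,
    TRD_SCALE,
    classify_re,
    encounter_potential,
    reported_presence,
    scale_trip_frequency,
    trip_duration_multiplier,
    village_re,
    villager_re,
)

# independent brute-force restatement of the published scalings
FT_TABLE = {
    "gt4_per_week": 260,
    "2to4_per_week": 156,
    "1to2_per_week": 78,
    "1to2_per_month": 18,
    "1to2_per_year": 2,
    "lt1_per_year": 1,
    "none": 0,
}
TRD_TABLE = {"0": 1.0, "1to4": 1.1, "gt4": 1.25}


@pytest.mark.parametrize("category,expected", sorted(FT_TABLE.items()))
def test_trip_frequency_scaling(category, expected):
    assert scale_trip_frequency(category) == expected


@pytest.mark.parametrize("category,expected", sorted(TRD_TABLE.items()))
def test_trip_duration_multiplier(category, expected):
    assert trip_duration_multiplier(category) == expected


def test_unknown_categories_raise():
    with pytest.raises(KeyError):
        scale_trip_frequency("5_per_day")
    with pytest.raises(KeyError):
        trip_duration_multiplier("7")


@pytest.mark.parametrize(
    "ever,year,expected",
    [("yes", "yes", 1.0), ("yes", "no", 0.0), ("no", "yes", 0.0), ("no", "no", 0.0)],
)
def test_reported_presence_requires_both(ever, year, expected):
    assert reported_presence(ever, year) == expected


def test_reported_presence_missing_propagates():
    assert np.isnan(reported_presence(None, "yes"))
    assert np.isnan(reported_presence("yes", np.nan))


def test_encounter_potential_cases():
    assert encounter_potential(156.0, 1.25, 1.0) == pytest.approx(195.0)
    assert encounter_potential(0.0, 1.0, 1.0) == 1.0  # saw one without entering forest
    assert encounter_potential(0.0, 1.0, 0.0) == 0.0


def test_re_matches_brute_force_over_all_cells():
    """RE over all 7 FT cells x 3 TrD cells x presence in {0,1} (42 cases)."""
    for trips, ft in FT_TABLE.items():
        for nights, trd in TRD_TABLE.items():
            for presence in (0.0, 1.0):
                # brute-force restatement of the definition
                pot = 1.0 if (presence == 1 and ft == 0) else ft * trd
                expected = 0.0 if pot == 0 else presence / pot
                got = villager_re(
                    scale_trip_frequency(trips), trip_duration_multiplier(nights), presence
                )
                assert got == pytest.approx(expected), (trips, nights, presence)


def test_re_non_increasing_in_exposure_when_present():
    """With one presence report, more forest exposure means lower RE."""
    for nights in TRD_TABLE:
        res = [
            villager_re(scale_trip_frequency(t), trip_duration_multiplier(nights), 1.0)
            for t in FT_TABLE  # ordered highest exposure first
        ]
        assert all(a <= b + 1e-12 for a, b in zip(res, res[1:]))


def _village_table(res, levels):
    return pd.DataFrame(
        {
            "village_id": ["A"] * len(res),
            "RE": res,
            "reliability_level": levels,
        }
    )


def test_village_re_mean_over_reliable_only():
    tab = _village_table([0.0, 0.0, 1 / 18, 5.0], [3, 2, 2, 1])  # last is unreliable
    out = village_re(tab)
    assert out.loc[0, "mean_RE"] == pytest.approx(1 / 54)
    assert out.loc[0, "n_reliable"] == 3


def test_village_re_no_reliable_respondents_missing_with_reason():
    out = village_re(_village_table([0.3, 0.1], [1, 1]))
    assert np.isnan(out.loc[0, "mean_RE"])
    assert out.loc[0, "re_reason"] == "no_reliable_respondents"


def test_village_re_single_reliable_zero():
    out = village_re(_village_table([0.0], [3]))
    assert out.loc[0, "mean_RE"] == 0.0


def test_village_re_permutation_invariant_and_matches_mean(scored_survey):
    v, _, _ = scored_survey
    base = village_re(v).set_index("village_id")["mean_RE"]
    shuffled = village_re(v.sample(frac=1.0, random_state=3)).set_index("village_id")["mean_RE"]
    pd.testing.assert_series_equal(base, shuffled)
    # brute-force mean for one village
    vid = base.dropna().index[0]
    grp = v[(v["village_id"] == vid) & (v["reliability_level"] > 1)]["RE"].dropna()
    assert base[vid] == pytest.approx(sum(grp) / len(grp))


def test_classify_re_zero_is_class_one():
    scores = pd.Series([0.0, 0.0, 0.01, 0.02, 0.03, 0.278])
    classes = classify_re(scores)
    assert classes[0] == 1 and classes[1] == 1
    assert classes[5] == 4  # top of the positive distribution


def test_classify_re_positive_tertiles():
    classes = classify_re(pd.Series([0.0, 0.01, 0.02, 0.03]))
    assert classes.tolist() == [1, 2, 3, 4]


def test_classify_re_all_zero_distribution():
    assert classify_re(pd.Series([0.0, 0.0])).tolist() == [1, 1]


def test_classify_re_missing_stays_missing():
    out = classify_re(pd.Series([0.0, np.nan, 0.5]))
    assert np.isnan(out[1])


def test_classify_re_quartile_scheme():
    out = classify_re(pd.Series([1.0, 2.0, 3.0, 4.0]), scheme="quartile")
    assert out.tolist() == [1, 2, 3, 4]
    with pytest.raises(ValueError):
        classify_re(pd.Series([1.0]), scheme="quintile")


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    scale=st.floats(min_value=1e-3, max_value=1e3),
    values=st.lists(st.floats(min_value=0, max_value=10, allow_nan=False), min_size=4, max_size=30),
)
def test_classify_re_scale_invariant(scale, values):
    """Class assignment is invariant under positive rescaling of all scores."""
    base = classify_re(pd.Series(values))
    scaled = classify_re(pd.Series([v * scale for v in values]))
    np.testing.assert_array_equal(base, scaled)


def test_lookup_tables_match_module_constants():
    assert FT_SCALE == {k: float(v) for k, v in FT_TABLE.items()}
    assert TRD_SCALE == TRD_TABLE
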
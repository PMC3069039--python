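import numpy as np
import pandas as pd
import pytest

from apesurvey.encounter import EncounterIndex
from apesurvey.reliability import ReliabilityScorer
from apesurvey.simulate import SimulationConfig, simulate_survey


@pytest.fixture(scope="session")
def survey_factory():
    """Factory for seeded synthetic surveys with optional overrides."""

    def make(seed=7, n_villages=150, **overrides):
        cfg = SimulationConfig(n_villages=n_villages, seed=seed, **overrides)
        return simulate_survey(cfg)

    return make


@pytest.fixture(scope="session")
def small_survey(survey_factory):
    """A complete (no missingness, no recall conflicts) 60-village survey."""
    return survey_factory(seed=7, n_villages=150, missing_rate=0.0, conflict_rate=0.0)


@pytest.fixture(scope="session")
def scored_survey(small_survey):
    """Small survey with reliability levels and RE columns attached."""
    villagers, villages, truth = small_survey
    v = ReliabilityScorer().fit_transform(villagers)
    v = EncounterIndex().fit_transform(v)
    return v, villages, truth


@pytest.fixture()
def tiny_villagers():
    """Hand-built 6-respondent, 2-village table for exact-value tests."""
    return pd.DataFrame(
        {
            "respondent_id": [f"R{i}" for i in range(6)],
            "village_id": ["A", "A", "A", "B", "B", "B"],
            "sex": ["male", "female", "male", "male", "male", "female"],
            "ans_orangutan": ["mawas", "orangutan", "monyet", "mawas", "mawas", "mawas"],
            "ans_red_langur": ["kelasi", "kera", "kelasi", "kelasi", "kelasi", "kelasi"],
            "ans_gibbon": ["owa", "owa", "owa", "owa", "owa", "owa"],
            "ans_douc_langur": ["kera"] * 6,
            "trips_category": ["1to2_per_month", "none", "gt4_per_week",
                               "1to2_per_month", "none", "2to4_per_week"],
            "nights_category": ["0", "0", "1to4", "0", "0", "gt4"],
            "ever_seen": ["yes", "no", "yes", "yes", "yes", "no"],
            "seen_last_year": ["yes", "no", "yes", "yes", "no", "no"],
            "seen_last_month": ["no", "no", "yes", "no", "no", "no"],
            "seen_last_week": ["no", "no", "no", "no", "no", "no"],
            "n_seen_last_year": [2.0, 0.0, 1.0, 1.0, 0.0, 0.0],
            "location_precision": [1.0, np.nan, 3.0, 2.0, 5.0, np.nan],
            "selection_method": ["random", "random", "suggested",
                                 "volunteered", "random", "random"],
        }
    )
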
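"""Relative Encounter (RE) index.

RE relates a respondent's reported orangutan presence over the past year to
a scaled measure of their exposure to forest:

    RE = reported presence / potential of encountering

where the encounter potential is the scaled annual forest-trip frequency
(FT) times a trip-duration multiplier (TrD).  The FT scaling was developed
by field experts to differentiate propensity to observe the species; TrD
inflates exposure for respondents who stay nights in the forest.  A
respondent who saw an orangutan but reported no forest trips gets potential
one, so a report never divides by zero.

RE is relative: it orders villages by encounter rate but is not an absolute
abundance or density.  Village-level RE is the mean over *reliable*
respondents only (reliability level > 1) and is mapped to four classes —
class 1 for exactly zero, classes 2–4 by tertiles of the strictly positive
village means (a plain all-value quartile scheme is available via
``scheme="quartile"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "FT_SCALE",
    "TRD_SCALE",
    "scale_trip_frequency",
    "trip_duration_multiplier",
    "reported_presence",
    "encounter_potential",
    "villager_re",
    "village_re",
    "classify_re",
    "EncounterIndex",
]

#: scaled annual trips by frequency category (expert-elicited)
FT_SCALE = {
    "gt4_per_week": 260.0,
    "2to4_per_week": 156.0,
    "1to2_per_week": 78.0,
    "1to2_per_month": 18.0,
    "1to2_per_year": 2.0,
    "lt1_per_year": 1.0,
    "none": 0.0,
}

#: trip-duration multiplier by nights-per-trip category; exactly 4 nights
#: falls in the 1-4 cell, strictly more than 4 in the top cell
TRD_SCALE = {"0": 1.0, "1to4": 1.1, "gt4": 1.25}


def scale_trip_frequency(trips_category: str) -> float:
    """FT lookup: forest-trip category -> scaled trips/year."""
    try:
        return FT_SCALE[trips_category]
    except KeyError:
        raise KeyError(f"unknown trips category {trips_category!r}; expected one of {sorted(FT_SCALE)}")


def trip_duration_multiplier(nights_category: str) -> float:
    """TrD lookup: nights-per-trip category -> multiplier of FT."""
    try:
        return TRD_SCALE[nights_category]
    except KeyError:
        raise KeyError(f"unknown nights category {nights_category!r}; expected one of {sorted(TRD_SCALE)}")


def reported_presence(ever_seen, seen_last_year):
    """Binary Reported Presence: saw one in the past year AND had previously
    seen one near the village.  Missing in either answer propagates."""
    if pd.isna(ever_seen) or pd.isna(seen_last_year):
        return np.nan
    return float(ever_seen == "yes" and seen_last_year == "yes")


def encounter_potential(ft: float, trd: float, presence: float) -> float:
    """Encounter potential FT x TrD; a respondent reporting presence without
    entering the forest (FT = 0) is assigned potential one."""
    if presence == 1 and ft == 0:
        return 1.0
    return ft * trd


def villager_re(ft: float, trd: float, presence: float) -> float:
    """Individual-level RE = presence / potential (0/0 -> 0; missing
    presence -> missing RE, never imputed here)."""
    if pd.isna(presence):
        return np.nan
    potential = encounter_potential(ft, trd, presence)
    if potential == 0.0:
        return 0.0  # presence is necessarily 0 here
    return presence / potential


@dataclass
class VillageRE:
    village_id: str
    mean_RE: float  # NaN when no reliable respondent has a computable RE
    n_reliable: int
    reason: str | None = None


def village_re(villagers: pd.DataFrame) -> pd.DataFrame:
    """Village-level mean RE over reliable respondents (level > 1).

    Expects ``RE`` and ``reliability_level`` columns (see
    :class:`EncounterIndex`).  Villages with no reliable, computable RE get
    ``mean_RE`` missing with a reason.
    """
    rows = []
    for vid, grp in villagers.groupby("village_id", sort=True):
        reliable = grp[grp["reliability_level"] > 1]
        res = reliable["RE"].dropna()
        if len(res) == 0:
            reason = "no_reliable_respondents" if len(reliable) == 0 else "re_not_computable"
            rows.append((vid, np.nan, len(reliable), reason))
        else:
            rows.append((vid, float(res.mean()), len(reliable), None))
    return pd.DataFrame(rows, columns=["village_id", "mean_RE", "n_reliable", "re_reason"])


def classify_re(mean_re: pd.Series | np.ndarray, scheme: str = "zero_tertile") -> np.ndarray:
    """Map village mean-RE scores to 4 ordinal classes.

    ``zero_tertile`` (default): class 1 = exactly zero; classes 2-4 are the
    tertiles of the strictly positive distribution, boundary values going to
    the lower class.  ``quartile``: plain quartiles over all values.
    Missing scores stay missing.
    """
    x = np.asarray(pd.Series(mean_re), dtype=float)
    out = np.full(x.shape, np.nan)
    obs = ~np.isnan(x)
    if scheme == "zero_tertile":
        out[obs & (x == 0)] = 1
        pos = x[obs & (x > 0)]
        if pos.size:
            lo, hi = np.quantile(pos, [1 / 3, 2 / 3])
            sel = obs & (x > 0)
            out[sel] = np.where(x[sel] <= lo, 2, np.where(x[sel] <= hi, 3, 4))
    elif scheme == "quartile":
        vals = x[obs]
        if vals.size:
            q = np.quantile(vals, [0.25, 0.5, 0.75])
            out[obs] = 1 + (vals[None, :] > q[:, None]).sum(axis=0)
    else:
        raise ValueError(f"unknown classing scheme {scheme!r}")
    return out


class EncounterIndex(BaseEstimator, TransformerMixin):
    """Transformer adding FT, TrD, potential, presence and RE columns to a
    villager table, with village-level aggregation.

    Parameters
    ----------
    scheme : str
        RE classing scheme passed to :func:`classify_re`.
    """

    def __init__(self, scheme: str = "zero_tertile"):
        self.scheme = scheme

    def fit(self, X: pd.DataFrame, y=None):
        del X, y
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        out["FT"] = out["trips_category"].map(FT_SCALE)
        out["TrD"] = out["nights_category"].map(TRD_SCALE)
        out["presence"] = [
            reported_presence(e, s) for e, s in zip(out["ever_seen"], out["seen_last_year"])
        ]
        out["potential"] = [
            np.nan if (pd.isna(f) or pd.isna(t) or pd.isna(p)) else encounter_potential(f, t, p)
            for f, t, p in zip(out["FT"], out["TrD"], out["presence"])
        ]
        out["RE"] = [
            np.nan if (pd.isna(f) or pd.isna(t)) else villager_re(f, t, p)
            for f, t, p in zip(out["FT"], out["TrD"], out["presence"])
        ]
        return out

    def village_table(self, villagers: pd.DataFrame) -> pd.DataFrame:
        """Aggregate a transformed villager table to villages and class RE."""
        vt = village_re(villagers)
        vt["re_class"] = classify_re(vt["mean_RE"], scheme=self.scheme)
        return vt
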
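"""Synthetic questionnaire generator emulating a stratified two-level
interview survey of villagers about great-ape encounters.

The generator reproduces the statistical structure the downstream analysis
assumes: a village sampling frame stratified by land-use threat (all
high-threat villages sampled, a random subset of the rest, ~40% overall),
ten respondents per village, a respondent-reliability mixture, village-level
clustering of sighting responses through a random intercept on the logit
scale, a small rate of contradictory temporal-recall answers, occasional
villages whose species-identification answers are byte-identical (imitating
group interviews or fabricated records), and MCAR missingness.

Every stochastic field draws from its own named substream derived from the
seed, so adding a field never perturbs earlier draws and the same seed gives
byte-identical output tables.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .schema import (
    ETHNICITY_CATEGORIES,
    NIGHTS_CATEGORIES,
    PROVINCE_CATEGORIES,
    RELIGION_CATEGORIES,
    SELECTION_CATEGORIES,
    THREAT_CATEGORIES,
    TRIPS_CATEGORIES,
)
from .encounter import scale_trip_frequency

__all__ = ["SimulationConfig", "SurveyTruth", "simulate_survey", "inject_missingness"]


class ConfigurationError(ValueError):
    """Invalid simulation configuration (fractions outside [0,1], mixtures
    not summing to one, inconsistent stratum/fraud settings)."""


#: vernacular synonym pools used for free-text species-name answers; the
#: first entries are treated as correct by the default answer key.
CORRECT_NAMES = {
    "orangutan": ("orangutan", "orang utan", "mawas", "maias", "kahiyu"),
    "red_langur": ("red langur", "kelasi", "lutung merah"),
    "gibbon": ("gibbon", "owa", "kelempiau", "wakwak"),
    "douc_langur": ("douc langur",),
}
WRONG_NAMES = ("monyet", "kera", "beruk", "lutung", "tidak tahu", "bekantan")


@dataclass
class SimulationConfig:
    """Generating parameters for one synthetic survey.

    ``n_villages`` is the size of the sampling *frame*; the number of
    interviewed villages emerges as roughly ``sampling_fraction *
    n_villages`` (every high-threat village plus a random subset of the
    others, mirroring the study's two-level design).
    """

    n_villages: int = 1725
    respondents_per_village: int = 10
    stratum_proportions: tuple[float, float, float] = (0.15, 0.45, 0.40)  # high/med/low
    sampling_fraction: float = 0.40
    base_presence_logit: float = -1.0
    village_random_sd: float = 1.0
    covariate_effects: dict[str, float] = field(default_factory=lambda: {"log_ft": 0.25})
    reliability_mix: tuple[float, float, float] = (0.701, 0.132, 0.167)  # levels 3/2/1
    missing_rate: float = 0.05
    conflict_rate: float = 0.02
    fraud_village_rate: float = 0.086
    male_fraction: float = 0.888
    seed: int = 0

    # implementer-chosen categorical distributions (the survey instrument
    # defines the cells, not their frequencies)
    trips_probs: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.15, 0.10, 0.25)
    nights_probs: tuple[float, float, float] = (0.60, 0.30, 0.10)
    precision_probs: tuple[float, ...] = (0.30, 0.30, 0.26, 0.09, 0.05)
    selection_probs: tuple[float, float, float] = (0.64, 0.18, 0.18)
    ethnicity_probs: tuple[float, ...] = (0.663, 0.168, 0.165, 0.004)
    religion_probs: tuple[float, ...] = (0.48, 0.48, 0.04)
    # west/central/east shares of the village frame (558/976/183 villages)
    province_probs: tuple[float, float, float] = (558 / 1717, 976 / 1717, 183 / 1717)

    def validate(self) -> None:
        fracs = {
            "sampling_fraction": self.sampling_fraction,
            "missing_rate": self.missing_rate,
            "conflict_rate": self.conflict_rate,
            "fraud_village_rate": self.fraud_village_rate,
            "male_fraction": self.male_fraction,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        for name, mix in (
            ("stratum_proportions", self.stratum_proportions),
            ("reliability_mix", self.reliability_mix),
            ("trips_probs", self.trips_probs),
            ("nights_probs", self.nights_probs),
            ("precision_probs", self.precision_probs),
            ("selection_probs", self.selection_probs),
            ("ethnicity_probs", self.ethnicity_probs),
            ("religion_probs", self.religion_probs),
            ("province_probs", self.province_probs),
        ):
            arr = np.asarray(mix, dtype=float)
            if (arr < 0).any() or (arr > 1).any():
                raise ConfigurationError(f"{name} has entries outside [0, 1]")
            if abs(arr.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1 (got {arr.sum()!r})")
        if self.n_villages < 0 or self.respondents_per_village < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.village_random_sd < 0:
            raise ConfigurationError("village_random_sd must be >= 0")
        if self.fraud_village_rate > self.reliability_mix[2] + 1e-12:
            raise ConfigurationError(
                "fraud_village_rate cannot exceed the level-1 share of reliability_mix "
                "(fraud villages are demoted to level 1)"
            )


@dataclass
class SurveyTruth:
    """Generating parameters and latent draws, kept for recovery tests."""

    config: dict
    n_frame_villages: int
    n_sampled_villages: int
    n_respondents: int
    village_effects: dict[str, float]
    fraud_villages: list[str]
    conflict_respondents: list[str]
    true_levels: dict[str, int]
    mean_presence_prob: float

    def flat(self) -> dict:
        """Flat scalar key-value view for serialisation."""
        out = {}
        for k, v in self.config.items():
            if isinstance(v, dict):
                for kk, vv in v.items():
                    out[f"{k}.{kk}"] = vv
            elif isinstance(v, (list, tuple)):
                for i, vv in enumerate(v):
                    out[f"{k}.{i}"] = vv
            else:
                out[k] = v
        out["n_frame_villages"] = self.n_frame_villages
        out["n_sampled_villages"] = self.n_sampled_villages
        out["n_respondents"] = self.n_respondents
        out["n_fraud_villages"] = len(self.fraud_villages)
        out["n_conflict_respondents"] = len(self.conflict_respondents)
        out["mean_presence_prob"] = self.mean_presence_prob
        return out

    def write(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(self.flat(), indent=2, default=float) + "\n")


def _rng(seed: int, stream: str) -> np.random.Generator:
    # crc32 gives a stable name->int mapping; pairing it with the seed in a
    # SeedSequence yields independent per-field substreams
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(stream.encode())]))


def _choice(rng, options, probs, n):
    return rng.choice(np.asarray(options, dtype=object), size=n, p=np.asarray(probs, dtype=float))


def covariate_matrix(df: pd.DataFrame, names: list[str]) -> np.ndarray:
    """Design columns for the presence model, by covariate name.

    Supported names: ``male``, ``age_z`` ((age-40)/13), ``log_ft``
    (log1p of the scaled annual trip frequency), ``dayak``.
    """
    cols = []
    for name in names:
        if name == "male":
            cols.append((df["sex"] == "male").to_numpy(float))
        elif name == "age_z":
            cols.append(((pd.to_numeric(df["age"]) - 40.0) / 13.0).to_numpy(float))
        elif name == "log_ft":
            ft = df["trips_category"].map(scale_trip_frequency).to_numpy(float)
            cols.append(np.log1p(ft))
        elif name == "dayak":
            cols.append((df["ethnicity"] == "dayak").to_numpy(float))
        else:
            raise ConfigurationError(f"unknown covariate {name!r}")
    if not cols:
        return np.empty((len(df), 0))
    return np.column_stack(cols)


def _make_villages(config: SimulationConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Build the frame, stratify, and draw the two-level sample."""
    n = config.n_villages
    props = np.asarray(config.stratum_proportions, dtype=float)
    counts = np.floor(props * n).astype(int)
    counts[0] += n - counts.sum()  # remainder to the high stratum
    strata = np.repeat(np.asarray(THREAT_CATEGORIES, dtype=object), counts)

    rng = _rng(config.seed, "villages")
    province = _choice(rng, PROVINCE_CATEGORIES, config.province_probs, n)
    area = np.round(np.exp(rng.normal(np.log(120.0), 0.7, size=n)), 1)
    lat = np.round(rng.uniform(-3.5, 2.0, size=n), 5)
    lon = np.round(rng.uniform(109.0, 119.0, size=n), 5)

    frame = pd.DataFrame(
        {
            "village_id": [f"V{i + 1:05d}" for i in range(n)],
            "province": province,
            "threat_stratum": strata,
            "admin_area_km2": area,
            "latitude": lat,
            "longitude": lon,
        }
    )

    target = int(round(config.sampling_fraction * n))
    high_idx = np.flatnonzero(strata == "high")
    other_idx = np.flatnonzero(strata != "high")
    n_other = max(0, min(target - high_idx.size, other_idx.size))
    srng = _rng(config.seed, "village_sample")
    chosen_other = np.sort(srng.choice(other_idx, size=n_other, replace=False))
    sampled = np.sort(np.concatenate([high_idx, chosen_other]))
    return frame, sampled


def simulate_survey(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, SurveyTruth]:
    """Generate (villager table, village table, truth record).

    Sighting responses are drawn from a logistic model with village random
    intercepts; species-ID answers are consistent with each respondent's
    drawn reliability level; fraud villages get byte-identical species-ID
    blocks.  ``config.missing_rate`` is applied afterwards via
    :func:`inject_missingness` (ids never masked).
    """
    config.validate()
    frame, sampled_idx = _make_villages(config)
    villages = frame.iloc[sampled_idx].reset_index(drop=True).copy()
    m = len(villages)
    k = config.respondents_per_village
    n = m * k
    villages["n_respondents"] = k

    if n == 0:
        empty = _empty_villager_table()
        truth = SurveyTruth(
            config=asdict(config), n_frame_villages=config.n_villages,
            n_sampled_villages=m, n_respondents=0, village_effects={},
            fraud_villages=[], conflict_respondents=[], true_levels={},
            mean_presence_prob=float("nan"),
        )
        return empty, villages, truth

    vid = np.repeat(villages["village_id"].to_numpy(), k)
    rid = np.array([f"{v}-R{i + 1:02d}" for v, i in zip(vid, np.tile(np.arange(k), m))], dtype=object)

    # --- demographics -----------------------------------------------------
    sex = np.where(_rng(config.seed, "sex").random(n) < config.male_fraction, "male", "female")
    age = np.clip(np.round(_rng(config.seed, "age").normal(40, 13, n)), 16, 90).astype(int)
    ethnicity = _choice(_rng(config.seed, "ethnicity"), ETHNICITY_CATEGORIES, config.ethnicity_probs, n)
    religion = _choice(_rng(config.seed, "religion"), RELIGION_CATEGORIES, config.religion_probs, n)
    years = np.minimum(
        np.round(_rng(config.seed, "years").exponential(15.0, n)).astype(int), age - 10
    ).clip(min=0)
    selection = _choice(_rng(config.seed, "selection"), SELECTION_CATEGORIES, config.selection_probs, n)

    # --- forest exposure --------------------------------------------------
    trips = _choice(_rng(config.seed, "trips"), TRIPS_CATEGORIES, config.trips_probs, n)
    nights = _choice(_rng(config.seed, "nights"), NIGHTS_CATEGORIES, config.nights_probs, n)

    # --- reliability levels and species-ID answers ------------------------
    fraud_draw = _rng(config.seed, "fraud").random(m) < config.fraud_village_rate
    fraud_villages = villages["village_id"].to_numpy()[fraud_draw]
    p3, p2, p1 = config.reliability_mix
    f = config.fraud_village_rate
    # non-fraud respondents draw from rescaled probabilities so the marginal
    # level distribution matches reliability_mix despite fraud demotion
    if f < 1.0:
        adj = np.array([p3, p2, max(p1 - f, 0.0)]) / (1.0 - f)
        adj = adj / adj.sum()
    else:  # pragma: no cover - degenerate
        adj = np.array([0.0, 0.0, 1.0])
    levels = _choice(_rng(config.seed, "levels"), [3, 2, 1], adj, n).astype(int)
    is_fraud_row = np.isin(vid, fraud_villages)
    levels[is_fraud_row] = 1

    answers = _species_answers(config, levels, is_fraud_row, vid, m, k)

    # --- presence model ---------------------------------------------------
    demo = pd.DataFrame({"sex": sex, "age": age, "ethnicity": ethnicity, "trips_category": trips})
    names = sorted(config.covariate_effects)
    X = covariate_matrix(demo, names)
    beta = np.array([config.covariate_effects[c] for c in names], dtype=float)
    u = _rng(config.seed, "village_effects").normal(0.0, 1.0, m)
    eta = config.base_presence_logit + X @ beta + config.village_random_sd * np.repeat(u, k)
    p = expit(eta)
    prng = _rng(config.seed, "presence")
    seen_year = prng.random(n) < p
    ever_extra = _rng(config.seed, "ever_extra").random(n) < 0.30
    ever = seen_year | ever_extra
    mrng = _rng(config.seed, "months")
    seen_month = seen_year & (mrng.random(n) < 0.40)
    seen_week = seen_month & (mrng.random(n) < 0.40)
    n_seen = np.where(seen_year, 1 + _rng(config.seed, "n_seen").poisson(0.8, n), 0)

    # --- temporal-recall conflicts ----------------------------------------
    crng = _rng(config.seed, "conflicts")
    conflict_mask = ever & (crng.random(n) < config.conflict_rate)
    # shorter-window positive contradicting a longer-window negative
    seen_week = np.where(conflict_mask, True, seen_week)
    seen_year_rep = np.where(conflict_mask, False, seen_year)
    seen_month_rep = np.where(conflict_mask, False, seen_month)

    # --- sighting metadata -------------------------------------------------
    lrng = _rng(config.seed, "precision")
    precision = np.where(
        ever, lrng.choice([1, 2, 3, 4, 5], size=n, p=np.asarray(config.precision_probs)), np.nan
    )
    grng = _rng(config.seed, "conflict_garden")
    garden = grng.random(n) < expit(eta - 1.5)
    killed_village = _rng(config.seed, "killed_village").random(m) < expit(
        config.base_presence_logit + u - 1.0
    )
    kflip = _rng(config.seed, "killed_flip").random(n) < 0.10
    killed = np.repeat(killed_village, k) ^ kflip

    trng = _rng(config.seed, "times")
    start = pd.Timestamp("2008-04-01") + pd.to_timedelta(
        trng.integers(0, 450 * 24 * 60, n), unit="m"
    )
    dur_min = np.exp(trng.normal(np.log(20.0), 0.45, n))
    rushed = trng.random(n) < 0.02  # implausibly short interviews
    dur_min = np.where(rushed, trng.uniform(0.3, 0.95, n), dur_min)
    end = start + pd.to_timedelta(np.round(dur_min * 60).astype(int), unit="s")

    yn = lambda b: np.where(b, "yes", "no")
    villagers = pd.DataFrame(
        {
            "respondent_id": rid,
            "village_id": vid,
            "age": age,
            "sex": sex,
            "ethnicity": ethnicity,
            "religion": religion,
            "years_in_village": years,
            "selection_method": selection,
            **{c: answers[c] for c in answers},
            "trips_category": trips,
            "nights_category": nights,
            "ever_seen": yn(ever),
            "seen_last_year": yn(seen_year_rep),
            "seen_last_month": yn(seen_month_rep),
            "seen_last_week": yn(seen_week),
            "n_seen_last_year": n_seen,
            "location_precision": precision,
            "conflict_garden": yn(garden),
            "village_ever_killed": yn(killed),
            "interview_start": start.strftime("%Y-%m-%dT%H:%M:%S"),
            "interview_end": end.strftime("%Y-%m-%dT%H:%M:%S"),
        }
    )

    truth = SurveyTruth(
        config=asdict(config),
        n_frame_villages=config.n_villages,
        n_sampled_villages=m,
        n_respondents=n,
        village_effects=dict(zip(villages["village_id"], u)),
        fraud_villages=list(fraud_villages),
        conflict_respondents=list(rid[conflict_mask]),
        true_levels=dict(zip(rid, levels.tolist())),
        mean_presence_prob=float(p.mean()),
    )

    if config.missing_rate > 0:
        villagers = inject_missingness(
            villagers, config.missing_rate, seed=config.seed, mechanism="MCAR"
        )
    return villagers, villages, truth


def _species_answers(config, levels, is_fraud_row, vid, m, k):
    """Free-text photo answers consistent with each reliability level."""
    n = levels.size
    rng = _rng(config.seed, "species_answers")
    out: dict[str, np.ndarray] = {}

    def correct(species, size):
        pool = np.asarray(CORRECT_NAMES[species], dtype=object)
        return pool[rng.integers(0, len(pool), size)]

    def wrong(size):
        pool = np.asarray(WRONG_NAMES, dtype=object)
        return pool[rng.integers(0, len(pool), size)]

    ans_ou, ans_rl, ans_gb = correct("orangutan", n), correct("red_langur", n), correct("gibbon", n)
    lvl2_drop_gibbon = rng.random(n) < 0.5  # which second species level-2 knows
    lvl1_fail_ou = rng.random(n) < 0.6  # level-1 subtype: failed orangutan vs orangutan-only
    ans_rl = np.where(levels == 2, np.where(lvl2_drop_gibbon, ans_rl, wrong(n)), ans_rl)
    ans_gb = np.where(levels == 2, np.where(lvl2_drop_gibbon, wrong(n), ans_gb), ans_gb)
    l1 = levels == 1
    ans_ou = np.where(l1 & lvl1_fail_ou, wrong(n), ans_ou)
    ans_rl = np.where(l1, wrong(n), ans_rl)
    ans_gb = np.where(l1, wrong(n), ans_gb)
    ans_dl = wrong(n)  # false-positive control photo: never scored

    # fraud villages: copy the first respondent's answers to the whole block
    block = is_fraud_row.reshape(m, k)
    for name, arr in (("ans_orangutan", ans_ou), ("ans_red_langur", ans_rl),
                      ("ans_gibbon", ans_gb), ("ans_douc_langur", ans_dl)):
        a = arr.reshape(m, k).copy()
        fraud_rows = block.any(axis=1)
        a[fraud_rows] = a[fraud_rows, :1]
        out[name] = a.reshape(n)
    return out


def _empty_villager_table() -> pd.DataFrame:
    cols = [
        "respondent_id", "village_id", "age", "sex", "ethnicity", "religion",
        "years_in_village", "selection_method", "ans_orangutan", "ans_red_langur",
        "ans_gibbon", "ans_douc_langur", "trips_category", "nights_category",
        "ever_seen", "seen_last_year", "seen_last_month", "seen_last_week",
        "n_seen_last_year", "location_precision", "conflict_garden",
        "village_ever_killed", "interview_start", "interview_end",
    ]
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})


#: villager fields never masked (record identity)
ID_FIELDS = ("respondent_id", "village_id")


def inject_missingness(
    villagers: pd.DataFrame, rate: float, mechanism: str = "MCAR", seed: int = 0
) -> pd.DataFrame:
    """Mask each maskable cell independently with probability ``rate`` (MCAR).

    Identifier fields are never masked.  Returns a new table.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError(f"rate={rate} outside [0, 1]")
    if mechanism != "MCAR":
        raise ConfigurationError(f"unknown missingness mechanism {mechanism!r}")
    out = villagers.copy()
    if rate == 0.0 or out.empty:
        return out
    rng = _rng(seed, "missingness")
    maskable = [c for c in out.columns if c not in ID_FIELDS]
    mask = rng.random((len(out), len(maskable))) < rate
    for j, col in enumerate(maskable):
        col_mask = mask[:, j]
        if col_mask.any():
            out[col] = out[col].astype(object)
            out.loc[col_mask, col] = None
    return out
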
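"""Population extrapolation: demographic sampling ratios, stratum weights,
finite-population correction, and precision bounds.

Sample statistics from the interview survey are scaled to the village
population using (a) the ratio of sampled to frame villages per threat
stratum (all high-threat villages were sampled, so that stratum has weight
one), and (b) demographic ratios comparing respondent composition with
census counts.  Because a large fraction (~40%) of the frame was sampled,
a finite-population correction deflates the variances.  Villager-level
weights default to equal: the sample is taken as representative of the
sub-population with propensity to encounter the species, not of the census
population.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SurveyFrame",
    "PopulationEstimate",
    "demographic_ratios",
    "stratum_weights",
    "fpc_factor",
    "max_proportion_sd",
    "max_count_sd",
    "extrapolate_total",
]


@dataclass
class SurveyFrame:
    """Sampling-frame bookkeeping: villages per stratum in frame and sample,
    plus optional census demographics for ratio weighting."""

    frame_counts: dict[str, int]
    sample_counts: dict[str, int]
    census: pd.DataFrame | None = None  # columns: category, population
    n_frame_villages: int = 1725
    n_sample_villages: int = 687

    def validate(self) -> None:
        for s, n in self.sample_counts.items():
            if n < 0 or self.frame_counts.get(s, 0) < 0:
                raise ValueError(f"negative count in stratum {s!r}")
            if n > self.frame_counts.get(s, 0):
                raise ValueError(
                    f"stratum {s!r}: sample count {n} exceeds frame count {self.frame_counts.get(s, 0)}"
                )


@dataclass
class PopulationEstimate:
    point: float
    variance: float
    ci95: tuple[float, float]
    fpc_applied: bool
    weights_used: str
    notes: list[str] = field(default_factory=list)


def demographic_ratios(sample_counts: dict[str, int], census: dict[str, int]) -> dict[str, float]:
    """Per-category ratio of respondents to census population.

    Categories absent from the sample get ratio 0 with a warning; a census
    category with zero population but respondents present is inconsistent.
    """
    ratios = {}
    for cat, pop in census.items():
        n = sample_counts.get(cat, 0)
        if pop <= 0:
            if n > 0:
                raise ValueError(f"category {cat!r}: {n} respondents but zero census population")
            continue
        if n == 0:
            warnings.warn(f"category {cat!r} absent from the sample; ratio 0", stacklevel=2)
        ratios[cat] = n / pop
    return ratios


def stratum_weights(frame: SurveyFrame) -> dict[str, float]:
    """Village expansion weight per stratum: frame count / sample count.

    A fully sampled stratum (all high-threat villages) gets weight 1.
    Strata empty on both sides are excluded with a warning; a stratum with
    frame villages but none sampled cannot be weighted.
    """
    frame.validate()
    weights = {}
    for s, n_frame in frame.frame_counts.items():
        n_sample = frame.sample_counts.get(s, 0)
        if n_frame == 0 and n_sample == 0:
            warnings.warn(f"stratum {s!r} empty in frame and sample; excluded", stacklevel=2)
            continue
        if n_sample == 0:
            raise ValueError(f"stratum {s!r}: {n_frame} frame villages but none sampled")
        weights[s] = n_frame / n_sample
    return weights


def fpc_factor(n_sampled: int, n_frame: int, form: str = "simple") -> float:
    """Finite-population correction as a variance multiplier in (0, 1].

    ``simple``: 1 - n/N (default); ``classic``: (N - n)/(N - 1).  The two
    differ negligibly at study scale.
    """
    if not 0 < n_sampled <= n_frame:
        raise ValueError(f"need 0 < n_sampled <= n_frame, got {n_sampled}/{n_frame}")
    if form == "simple":
        return 1.0 - n_sampled / n_frame
    if form == "classic":
        return (n_frame - n_sampled) / (n_frame - 1) if n_frame > 1 else 0.0
    raise ValueError(f"unknown fpc form {form!r}")


def max_proportion_sd(n: int) -> float:
    """Worst-case standard deviation of an estimated proportion at sample
    size ``n``: sqrt(0.25/n), the binomial bound at p = 0.5."""
    if n <= 0:
        raise ValueError("n must be positive")
    return math.sqrt(0.25 / n)


def max_count_sd(n: int, expansion: float = 1.0) -> float:
    """Worst-case s.d. of a presence *count*: sqrt(n * 0.25), optionally
    scaled by a population expansion factor (e.g. frame/sample villages)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return math.sqrt(n * 0.25) * expansion


def extrapolate_total(
    sample_stat: float,
    sample_variance: float,
    n_sampled: int,
    n_frame: int,
    weight: float | None = None,
    apply_fpc: bool = True,
    fpc_form: str = "simple",
) -> PopulationEstimate:
    """Scale a sample total to the population with a normal-approximation CI.

    ``weight`` defaults to the expansion factor ``n_frame / n_sampled``.
    The variance scales by weight squared, then (optionally) by the FPC.
    """
    if sample_variance < 0:
        raise ValueError("negative sample variance")
    w = n_frame / n_sampled if weight is None else weight
    point = sample_stat * w
    variance = sample_variance * w**2
    notes = []
    if apply_fpc:
        factor = fpc_factor(n_sampled, n_frame, form=fpc_form)
        variance *= factor
        notes.append(f"fpc factor {factor:.4f} ({fpc_form})")
    if variance < 0:
        raise ValueError("negative variance after corrections; inconsistent inputs")
    half = 1.959963984540054 * math.sqrt(variance)
    return PopulationEstimate(
        point=point,
        variance=variance,
        ci95=(point - half, point + half),
        fpc_applied=apply_fpc,
        weights_used=f"uniform expansion weight {w:.4f}"
        if weight is None
        else f"user weight {w:.4f}",
        notes=notes,
    )


def bootstrap_total_ci(
    sample_values,
    weight: float,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Seeded percentile-bootstrap CI for a weighted total.

    Alternative to the normal approximation for small strata: resamples the
    per-unit values with replacement, scales each bootstrap total by
    ``weight``, and returns the percentile interval.
    """
    x = np.asarray(sample_values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    rng = np.random.default_rng(seed)
    totals = rng.choice(x, size=(n_boot, x.size), replace=True).sum(axis=1) * weight
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(totals, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def frame_from_villages(frame_table: pd.DataFrame, sample_table: pd.DataFrame,
                        census: pd.DataFrame | None = None) -> SurveyFrame:
    """Build a :class:`SurveyFrame` from frame and sampled village tables."""
    fc = frame_table["threat_stratum"].value_counts().to_dict()
    sc = sample_table["threat_stratum"].value_counts().to_dict()
    return SurveyFrame(
        frame_counts={k: int(v) for k, v in fc.items()},
        sample_counts={k: int(v) for k, v in sc.items()},
        census=census,
        n_frame_villages=int(len(frame_table)),
        n_sample_villages=int(len(sample_table)),
    )
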
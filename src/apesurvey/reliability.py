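"""Respondent reliability screening from photo species-identification.

Respondents were shown photographs of nine mammal species including three
focal primates — orangutan, red langur and Bornean gibbon.  Reliability is:

* level 3 (high): all three focal species correctly identified;
* level 2 (medium): orangutan plus at least one of the other two;
* level 1 (low): failed to recognise the orangutan, or knew only the
  orangutan; also every respondent in a village whose species-ID answers are
  byte-identical across all records (group interviews or fabrication are the
  plausible explanations, so the whole block is conservatively demoted).

Only respondents with level > 1 enter orangutan-related analyses.  A
missing photo answer counts as incorrect.  The false-positive control photo
(douc langur, not present on Borneo) is carried in the schema but never
scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .schema import FOCAL_SPECIES

__all__ = [
    "AnswerKey",
    "ReliabilityLevel",
    "classify_respondent",
    "flag_identical_blocks",
    "reliable_subset",
    "ReliabilityScorer",
]


def _default_key() -> dict[str, frozenset[str]]:
    return {
        "orangutan": frozenset({"orangutan", "orang utan", "mawas", "maias", "kahiyu"}),
        "red_langur": frozenset({"red langur", "kelasi", "lutung merah"}),
        "gibbon": frozenset({"gibbon", "owa", "kelempiau", "wakwak"}),
    }


@dataclass(frozen=True)
class AnswerKey:
    """Accepted (vernacular) names per focal species.

    Which local names count as correct is a field decision; the default key
    mirrors the synonym pools the synthetic generator draws from.  Matching
    is case-insensitive after whitespace stripping.
    """

    accepted: dict[str, frozenset[str]] = field(default_factory=_default_key)

    def is_correct(self, species: str, answer) -> bool:
        if answer is None or (isinstance(answer, float) and pd.isna(answer)):
            return False  # missing answer counts as incorrect
        return str(answer).strip().lower() in self.accepted[species]


@dataclass(frozen=True)
class ReliabilityLevel:
    level: int  # 1, 2 or 3
    reason: str  # high | medium | orangutan_only | failed_orangutan | identical_block


def classify_respondent(answers: dict, key: AnswerKey | None = None) -> ReliabilityLevel:
    """Deterministic reliability level from the three focal photo answers.

    ``answers`` maps ``ans_<species>`` (or bare species name) to the
    free-text response.
    """
    key = key or AnswerKey()
    correct = {}
    for sp in FOCAL_SPECIES:
        ans = answers.get(f"ans_{sp}", answers.get(sp))
        correct[sp] = key.is_correct(sp, ans)
    if all(correct.values()):
        return ReliabilityLevel(3, "high")
    if correct["orangutan"] and (correct["red_langur"] or correct["gibbon"]):
        return ReliabilityLevel(2, "medium")
    if correct["orangutan"]:
        return ReliabilityLevel(1, "orangutan_only")
    return ReliabilityLevel(1, "failed_orangutan")


#: columns compared byte-for-byte when detecting identical village blocks
ANSWER_FIELDS = ("ans_orangutan", "ans_red_langur", "ans_gibbon", "ans_douc_langur")


def flag_identical_blocks(villagers: pd.DataFrame) -> set[str]:
    """Villages where every respondent's species-ID answers (including the
    free-text names and the control photo) are byte-identical.

    Single-respondent villages are never flagged.  Row order is irrelevant.
    """
    cols = [c for c in ANSWER_FIELDS if c in villagers.columns]
    flagged = set()
    for vid, grp in villagers.groupby("village_id"):
        if len(grp) < 2:
            continue
        block = grp[cols].astype(str)
        if (block.nunique(dropna=False) == 1).all():
            flagged.add(vid)
    return flagged


def reliable_subset(villagers: pd.DataFrame) -> pd.DataFrame:
    """Respondents usable in orangutan analyses: reliability level > 1."""
    if "reliability_level" not in villagers.columns:
        raise ValueError("reliability_level not assigned; run ReliabilityScorer first")
    return villagers[villagers["reliability_level"] > 1].copy()


class ReliabilityScorer(BaseEstimator, TransformerMixin):
    """Transformer adding ``reliability_level`` and ``reliability_reason``.

    Applies the per-respondent photo rule, then demotes every respondent in
    an identical-answer village block to level 1.
    """

    def __init__(self, key: AnswerKey | None = None):
        self.key = key

    def fit(self, X: pd.DataFrame, y=None):
        del X, y
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        key = self.key or AnswerKey()
        out = X.copy()
        scored = [
            classify_respondent({c: row[c] for c in ANSWER_FIELDS if c in X.columns}, key)
            for _, row in X.iterrows()
        ]
        out["reliability_level"] = [s.level for s in scored]
        out["reliability_reason"] = [s.reason for s in scored]
        blocked = flag_identical_blocks(X)
        if blocked:
            mask = out["village_id"].isin(blocked)
            out.loc[mask, "reliability_level"] = 1
            out.loc[mask, "reliability_reason"] = "identical_block"
        return out
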
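"""Questionnaire data model: vocabularies, validation, and CSV input/output.

Two tables drive the pipeline:

* the **villager table** — one row per interviewed respondent (demographics,
  photo species-identification answers, forest-trip frequency and duration
  categories, orangutan sighting responses over nested timeframes, conflict
  and killing questions, interview metadata);
* the **village table** — one row per sampled village (province, land-use
  threat stratum, administrative area, coordinates).

Category labels are stored as ASCII tokens (e.g. ``gt4_per_week``); the
mapping to survey phrasing lives in :data:`TRIPS_LABELS` etc.  Missing values
are empty cells on disk; the literal strings ``NA``/``na`` are accepted on
read but never written.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

#: 7-cell forest-trip frequency scale, highest exposure first.
TRIPS_CATEGORIES = (
    "gt4_per_week",
    "2to4_per_week",
    "1to2_per_week",
    "1to2_per_month",
    "1to2_per_year",
    "lt1_per_year",
    "none",
)

TRIPS_LABELS = {
    "gt4_per_week": ">4 trips/week",
    "2to4_per_week": "2-4 trips/week",
    "1to2_per_week": "1-2 trips/week",
    "1to2_per_month": "1-2 trips/month",
    "1to2_per_year": "1-2 trips/year",
    "lt1_per_year": "<1 trips/year",
    "none": "0 trips",
}

#: nights spent in the forest per trip
NIGHTS_CATEGORIES = ("0", "1to4", "gt4")

YESNO = ("yes", "no")
SEX_CATEGORIES = ("male", "female")
ETHNICITY_CATEGORIES = ("dayak", "malay_banjar_kutai", "immigrant", "formerly_nomadic")
RELIGION_CATEGORIES = ("islam", "christian", "other")
SELECTION_CATEGORIES = ("random", "suggested", "volunteered")
PROVINCE_CATEGORIES = ("west", "central", "east")
THREAT_CATEGORIES = ("high", "medium", "low")

#: photo species-ID answer columns; the douc langur is the false-positive
#: control photo — carried through but ignored by reliability scoring.
FOCAL_SPECIES = ("orangutan", "red_langur", "gibbon")
ANSWER_COLUMNS = tuple(f"ans_{s}" for s in FOCAL_SPECIES + ("douc_langur",))

#: villager-table vocabulary constraints checked on read
VILLAGER_VOCAB: dict[str, tuple[str, ...]] = {
    "sex": SEX_CATEGORIES,
    "ethnicity": ETHNICITY_CATEGORIES,
    "religion": RELIGION_CATEGORIES,
    "selection_method": SELECTION_CATEGORIES,
    "trips_category": TRIPS_CATEGORIES,
    "nights_category": NIGHTS_CATEGORIES,
    "ever_seen": YESNO,
    "seen_last_year": YESNO,
    "seen_last_month": YESNO,
    "seen_last_week": YESNO,
    "conflict_garden": YESNO,
    "village_ever_killed": YESNO,
}

VILLAGER_REQUIRED = ("respondent_id", "village_id")
VILLAGER_NUMERIC = ("age", "years_in_village", "n_seen_last_year", "location_precision")

VILLAGE_REQUIRED = ("village_id", "province", "threat_stratum")
VILLAGE_VOCAB: dict[str, tuple[str, ...]] = {
    "province": PROVINCE_CATEGORIES,
    "threat_stratum": THREAT_CATEGORIES,
}
VILLAGE_NUMERIC = ("admin_area_km2", "latitude", "longitude", "n_respondents")

MISSING_TOKENS = ("", "NA", "na")


class SchemaError(ValueError):
    """A table violates its schema in strict mode (missing columns, bad
    vocabulary, duplicate ids, orphan respondents)."""


@dataclass
class ValidationReport:
    """Collects per-row validation problems found while reading a table."""

    entries: list[dict] = field(default_factory=list)

    def add(self, row: int, column: str, value, problem: str) -> None:
        self.entries.append(
            {"row": int(row), "column": column, "value": None if value is None else str(value), "problem": problem}
        )

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.entries)

    @property
    def ok(self) -> bool:
        return not self.entries

    def to_text(self) -> str:
        if not self.entries:
            return "validation: clean\n"
        lines = [
            f"row {e['row']}: {e['column']}={e['value']!r}: {e['problem']}"
            for e in self.entries
        ]
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps({"n_problems": len(self.entries), "problems": self.entries}, indent=2)


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        dtype=str,
        keep_default_na=False,
        na_values=list(MISSING_TOKENS),
        skipinitialspace=False,
    )


def _coerce_numeric(df: pd.DataFrame, columns, report: ValidationReport, strict: bool) -> None:
    for col in columns:
        if col not in df.columns:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        for idx in df.index[bad]:
            if strict:
                raise SchemaError(f"column {col!r}, row {idx}: non-numeric value {df.at[idx, col]!r}")
            report.add(idx, col, df.at[idx, col], "non-numeric; set missing")
        df[col] = converted


def _check_vocab(df: pd.DataFrame, vocab, report: ValidationReport, strict: bool) -> None:
    for col, allowed in vocab.items():
        if col not in df.columns:
            continue
        bad = df[col].notna() & ~df[col].isin(allowed)
        for idx in df.index[bad]:
            if strict:
                raise SchemaError(
                    f"column {col!r}, row {idx}: {df.at[idx, col]!r} not in vocabulary {allowed}"
                )
            report.add(idx, col, df.at[idx, col], "not in vocabulary; set missing")
            df.at[idx, col] = None


def read_villagers(path, strict: bool = False) -> tuple[pd.DataFrame, ValidationReport]:
    """Read a villager table from CSV, validating vocabularies.

    In strict mode any violation raises :class:`SchemaError`; in lenient mode
    offending cells are coerced to missing and logged in the report.
    Unknown columns (e.g. opaque pass-through questionnaire items) are kept.
    """
    df = _read_csv(path)
    missing_cols = [c for c in VILLAGER_REQUIRED if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"villager table missing required columns: {missing_cols}")
    report = ValidationReport()
    _check_vocab(df, VILLAGER_VOCAB, report, strict)
    _coerce_numeric(df, VILLAGER_NUMERIC, report, strict)
    if "location_precision" in df.columns:
        lp = df["location_precision"]
        bad = lp.notna() & ~lp.isin([1, 2, 3, 4, 5])
        for idx in df.index[bad]:
            if strict:
                raise SchemaError(f"location_precision out of 1..5 at row {idx}: {lp[idx]}")
            report.add(idx, "location_precision", lp[idx], "outside 1..5; set missing")
            df.at[idx, "location_precision"] = None
    return df, report


def read_villages(path, strict: bool = False) -> tuple[pd.DataFrame, ValidationReport]:
    """Read a village table from CSV; village ids must be unique."""
    df = _read_csv(path)
    missing_cols = [c for c in VILLAGE_REQUIRED if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"village table missing required columns: {missing_cols}")
    report = ValidationReport()
    dup = df["village_id"].duplicated(keep=False)
    if dup.any():
        rows = df.index[dup].tolist()
        if strict:
            raise SchemaError(f"duplicate village_id values at rows {rows}")
        for idx in rows:
            report.add(idx, "village_id", df.at[idx, "village_id"], "duplicate id")
    _check_vocab(df, VILLAGE_VOCAB, report, strict)
    _coerce_numeric(df, VILLAGE_NUMERIC, report, strict)
    return df, report


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table as UTF-8 CSV (RFC 4180 quoting, empty cells for missing)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, na_rep="")


def join_levels(
    villagers: pd.DataFrame, villages: pd.DataFrame, strict: bool = False
) -> tuple[pd.DataFrame, ValidationReport]:
    """Attach village-level fields to each villager (the two-level nesting).

    Villagers whose ``village_id`` is absent from the village table are
    orphans: an error in strict mode, dropped and reported otherwise.
    """
    report = ValidationReport()
    known = set(villages["village_id"])
    orphan = ~villagers["village_id"].isin(known)
    if orphan.any():
        if strict:
            rows = villagers.index[orphan].tolist()
            raise SchemaError(f"orphan villagers (village_id not in village table) at rows {rows}")
        for idx in villagers.index[orphan]:
            report.add(idx, "village_id", villagers.at[idx, "village_id"], "orphan villager; dropped")
    joined = villagers.loc[~orphan].merge(
        villages, on="village_id", how="left", suffixes=("", "_village")
    )
    return joined, report
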
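"""Healthy-reference inclusion criteria, age classes and diet-cohort logic.

A cat enters the healthy reference set when its survey record shows an
acceptable body condition (body condition score 3-6 inclusive, or a BMI of
at most 50), no clinical signs, no diagnoses, no antibiotics in the previous
twelve months, none of a short list of excluded medications, an age between
0.5 and 12 years inclusive, and a private-home living environment.  Records
with missing data in any required field are excluded, and every failed
criterion is reported, not just the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "CatMetadata",
    "HealthyCriteria",
    "AgeClassBounds",
    "is_healthy_reference",
    "assign_age_class",
    "effective_fiv_status",
    "select_diet_cohort",
    "read_metadata",
    "write_metadata",
    "OUT_OF_RANGE",
]

#: tokens treated as "no entry" when normalizing free-text set fields
_NULL_TOKENS = {"", "none", "n/a", "na", "no"}

OUT_OF_RANGE = "out_of_range"


def normalize_tokens(values: Iterable[str]) -> frozenset[str]:
    """Lower-case, strip, and drop null-ish survey tokens ('None', '')."""
    out = set()
    for v in values:
        tok = str(v).strip().lower()
        if tok not in _NULL_TOKENS:
            out.add(tok)
    return frozenset(out)


@dataclass
class CatMetadata:
    """One cat's survey record (the fields that drive inclusion filters)."""

    cat_id: str
    age_years: Optional[float] = None
    body_condition_score: Optional[int] = None
    bmi: Optional[float] = None
    fecal_score: Optional[int] = None
    clinical_signs: frozenset[str] = frozenset()
    diagnoses: frozenset[str] = frozenset()
    antibiotics_last_12mo: Optional[bool] = None
    medications: frozenset[str] = frozenset()
    environment: str = "home"  # "home" | "shelter"
    fiv_status: str = "unknown"  # "positive" | "negative" | "unknown"
    diet_dry: Optional[bool] = None
    diet_wet: Optional[bool] = None
    diet_raw: Optional[bool] = None
    sex: Optional[str] = None
    spay_neuter: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.age_years is not None and self.age_years < 0:
            raise ValueError(f"{self.cat_id}: negative age")
        if self.environment not in ("home", "shelter"):
            raise ValueError(f"{self.cat_id}: unknown environment {self.environment!r}")
        self.clinical_signs = normalize_tokens(self.clinical_signs)
        self.diagnoses = normalize_tokens(self.diagnoses)
        self.medications = normalize_tokens(self.medications)


@dataclass
class HealthyCriteria:
    bcs_range: tuple[int, int] = (3, 6)
    bmi_max: float = 50.0
    age_range_years: tuple[float, float] = (0.5, 12.0)
    excluded_medications: frozenset[str] = frozenset(
        {"probiotics", "steroids", "sucralfate", "oclacitinib", "cetirizine", "benazepril"}
    )
    require_home: bool = True

    def __post_init__(self) -> None:
        if self.bcs_range[0] > self.bcs_range[1]:
            raise ValueError("empty BCS interval")
        if self.age_range_years[0] > self.age_range_years[1]:
            raise ValueError("empty age interval")
        self.excluded_medications = frozenset(
            m.strip().lower() for m in self.excluded_medications
        )


def is_healthy_reference(
    m: CatMetadata, c: HealthyCriteria | None = None
) -> tuple[bool, list[str]]:
    """Evaluate the healthy-reference criteria; total, never raises.

    Returns ``(ok, failed_codes)`` where ``failed_codes`` lists every failed
    criterion ("age", "bcs_bmi", ...) and ``missing:<field>`` for required
    fields absent from the record.
    """
    c = c or HealthyCriteria()
    failures: list[str] = []

    # body condition: BCS in range OR BMI <= max (a disjunction); a record
    # missing both cannot be evaluated and fails as missing
    if m.body_condition_score is None and m.bmi is None:
        failures.append("missing:body_condition")
    else:
        ok_bcs = (
            m.body_condition_score is not None
            and c.bcs_range[0] <= m.body_condition_score <= c.bcs_range[1]
        )
        ok_bmi = m.bmi is not None and m.bmi <= c.bmi_max
        if not (ok_bcs or ok_bmi):
            failures.append("bcs_bmi")

    if m.clinical_signs:
        failures.append("clinical_signs")
    if m.diagnoses:
        failures.append("diagnoses")

    if m.antibiotics_last_12mo is None:
        failures.append("missing:antibiotics")
    elif m.antibiotics_last_12mo:
        failures.append("antibiotics")

    if m.age_years is None:
        failures.append("missing:age")
    elif not (c.age_range_years[0] <= m.age_years <= c.age_range_years[1]):
        failures.append("age")

    if m.medications & c.excluded_medications:
        failures.append("medications")

    if c.require_home and m.environment != "home":
        failures.append("environment")

    return (not failures, failures)


@dataclass
class AgeClassBounds:
    """Ordered age classes in months; half-open intervals, last one closed.

    Boundary ages (exactly 3, 7 or 12 years) go to the older class.
    """

    classes: tuple[tuple[str, float, float], ...] = (
        ("junior", 7.0, 36.0),
        ("prime", 36.0, 84.0),
        ("mature", 84.0, 144.0),
        ("senior", 144.0, 168.0),
    )

    def __post_init__(self) -> None:
        for (_, _, hi), (_, lo, _) in zip(self.classes, self.classes[1:]):
            if hi != lo:
                raise ValueError("age classes must be contiguous")

    @property
    def labels(self) -> list[str]:
        return [name for name, _, _ in self.classes]


def assign_age_class(age_years: float, b: AgeClassBounds | None = None) -> str:
    """Map an age in years to its class label, or ``OUT_OF_RANGE``."""
    if age_years < 0:
        raise ValueError("negative age")
    b = b or AgeClassBounds()
    months = age_years * 12.0
    last = len(b.classes) - 1
    for i, (name, lo, hi) in enumerate(b.classes):
        if lo <= months < hi or (i == last and months == hi):
            return name
    return OUT_OF_RANGE


def effective_fiv_status(m: CatMetadata) -> str:
    """FIV status for cohort labeling (never used in healthy filtering).

    Shelter cats without an explicit status are assumed negative, since FIV
    screening is near-universal at intake; home cats stay "unknown".
    """
    if m.fiv_status == "unknown" and m.environment == "shelter":
        return "negative"
    return m.fiv_status


def select_diet_cohort(
    cats: Sequence[CatMetadata],
) -> tuple[list[str], list[tuple[str, str]]]:
    """Split cats into the diet-analysis cohort and exclusions with reasons.

    Cats missing any diet component are excluded ("missing_diet"), as are
    cats fed both dry and raw food ("dry_and_raw" — a rare combination kept
    out of the diet models).
    """
    retained: list[str] = []
    excluded: list[tuple[str, str]] = []
    for m in cats:
        if m.diet_dry is None or m.diet_wet is None or m.diet_raw is None:
            excluded.append((m.cat_id, "missing_diet"))
        elif m.diet_dry and m.diet_raw:
            excluded.append((m.cat_id, "dry_and_raw"))
        else:
            retained.append(m.cat_id)
    return retained, excluded


# ---------------------------------------------------------------------------
# TSV serialization.  One row per cat; list-valued fields pipe-separated;
# booleans "Y"/"N", empty cell = missing.

_BOOL_FIELDS = ("antibiotics_last_12mo", "diet_dry", "diet_wet", "diet_raw", "spay_neuter")
_SET_FIELDS = ("clinical_signs", "diagnoses", "medications")
_NUM_FIELDS = ("age_years", "body_condition_score", "bmi", "fecal_score")

COLUMNS = (
    "cat_id",
    "age_years",
    "body_condition_score",
    "bmi",
    "fecal_score",
    "clinical_signs",
    "diagnoses",
    "antibiotics_last_12mo",
    "medications",
    "environment",
    "fiv_status",
    "diet_dry",
    "diet_wet",
    "diet_raw",
    "sex",
    "spay_neuter",
)


def _parse_bool(cell: str) -> Optional[bool]:
    cell = cell.strip().upper()
    if cell == "":
        return None
    if cell in ("Y", "YES", "TRUE", "1"):
        return True
    if cell in ("N", "NO", "FALSE", "0"):
        return False
    raise ValueError(f"cannot parse boolean cell {cell!r}")


def read_metadata(path: str | Path) -> list[CatMetadata]:
    """Read per-cat survey metadata from TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cats = []
    for _, row in df.iterrows():
        kwargs: dict = {"cat_id": row["cat_id"]}
        for f in _NUM_FIELDS:
            cell = row.get(f, "").strip()
            if cell:
                v = float(cell)
                kwargs[f] = int(v) if f in ("body_condition_score", "fecal_score") else v
        for f in _SET_FIELDS:
            cell = row.get(f, "").strip()
            kwargs[f] = frozenset(cell.split("|")) if cell else frozenset()
        for f in _BOOL_FIELDS:
            kwargs[f] = _parse_bool(row.get(f, ""))
        kwargs["environment"] = row.get("environment", "home").strip() or "home"
        kwargs["fiv_status"] = row.get("fiv_status", "unknown").strip() or "unknown"
        sex = row.get("sex", "").strip()
        kwargs["sex"] = sex or None
        cats.append(CatMetadata(**kwargs))
    return cats


def write_metadata(cats: Sequence[CatMetadata], path: str | Path) -> None:
    rows = []
    for m in cats:
        row = {}
        for col in COLUMNS:
            v = getattr(m, col)
            if v is None:
                row[col] = ""
            elif col in _BOOL_FIELDS:
                row[col] = "Y" if v else "N"
            elif col in _SET_FIELDS:
                row[col] = "|".join(sorted(v))
            else:
                row[col] = v
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
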
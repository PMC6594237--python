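"""Patient-level cohort records and mortality-capture classification.

Each patient in an EHR-derived cohort is compared against a gold-standard
mortality source (e.g., a national death index) and falls into one of four
cells:

==== =========================================================
cell meaning
==== =========================================================
A    true positive  -- death recorded in both sources
B    false positive -- death recorded in the EHR only
C    false negative -- death recorded in the gold standard only
D    true negative  -- no death recorded in either source
==== =========================================================

Classification depends only on the *presence* of the two death dates; a
patient whose sources disagree on the date value is still cell A.  From the
cell counts, mortality-capture sensitivity is ``a / (a + c)`` and
specificity is ``d / (b + d)``.

Dates are stored as days from an arbitrary study origin.  Months are
converted at 30.4375 days/month for reporting.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

#: Average Gregorian month length used for day <-> month conversion.
DAYS_PER_MONTH = 30.4375

COHORT_COLUMNS = [
    "patient_id",
    "index_date",
    "arm",
    "ehr_death_date",
    "gold_death_date",
    "last_activity_date",
]


class CohortError(ValueError):
    """Invalid cohort input (empty cohort, broken record invariants ...)."""


class MortalityCell(enum.Enum):
    """Classification of one patient's EHR death capture vs the gold standard."""

    A = "A"  # true positive
    B = "B"  # false positive
    C = "C"  # false negative
    D = "D"  # true negative


@dataclass(frozen=True)
class PatientRecord:
    """One patient: index date, arm, two optional death dates, last activity.

    Parameters
    ----------
    patient_id : str
        Opaque identifier.
    index_date : float
        Time origin for this patient, in days from the study origin.
    arm : str
        Comparison-group label, e.g. ``"experimental"`` / ``"control"``.
    ehr_death_date : float or None
        Death date recorded in the EHR-derived source, if any.
    gold_death_date : float or None
        Death date recorded in the gold-standard source, if any.
    last_activity_date : float
        Last structured activity (visit/administration) in the EHR; the
        censoring date when no death is used for a patient.
    """

    patient_id: str
    index_date: float
    arm: str
    ehr_death_date: Optional[float]
    gold_death_date: Optional[float]
    last_activity_date: float

    def __post_init__(self) -> None:
        if self.last_activity_date < self.index_date:
            raise CohortError(
                f"{self.patient_id}: last_activity_date precedes index_date"
            )
        if self.gold_death_date is not None:
            if self.gold_death_date < self.index_date:
                raise CohortError(
                    f"{self.patient_id}: gold_death_date precedes index_date"
                )
            if self.last_activity_date > self.gold_death_date:
                raise CohortError(
                    f"{self.patient_id}: last_activity_date after gold death"
                )
        if self.ehr_death_date is not None and self.ehr_death_date < self.index_date:
            raise CohortError(
                f"{self.patient_id}: ehr_death_date precedes index_date"
            )


@dataclass(frozen=True)
class ConfusionCounts:
    """Cell counts of a classified cohort with derived capture metrics."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise CohortError("cell counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def sensitivity(self) -> float:
        """Fraction of gold-standard deaths captured by the EHR, a/(a+c)."""
        if self.a + self.c == 0:
            raise CohortError("sensitivity undefined: no gold-standard deaths (a+c=0)")
        return self.a / (self.a + self.c)

    @property
    def specificity(self) -> float:
        """Fraction of gold-standard survivors without an EHR death, d/(b+d)."""
        if self.b + self.d == 0:
            raise CohortError("specificity undefined: no gold-standard survivors (b+d=0)")
        return self.d / (self.b + self.d)

    def to_dict(self) -> dict:
        out = {"a": self.a, "b": self.b, "c": self.c, "d": self.d}
        try:
            out["sensitivity"] = self.sensitivity
        except CohortError:
            out["sensitivity"] = None
        try:
            out["specificity"] = self.specificity
        except CohortError:
            out["specificity"] = None
        return out


def classify_patient(record: PatientRecord) -> MortalityCell:
    """Classify one patient by the presence of the two death dates.

    Only presence matters; the date values never affect the cell.
    """
    has_ehr = record.ehr_death_date is not None
    has_gold = record.gold_death_date is not None
    if has_ehr and has_gold:
        return MortalityCell.A
    if has_ehr:
        return MortalityCell.B
    if has_gold:
        return MortalityCell.C
    return MortalityCell.D


def tabulate_cells(cohort: Sequence[PatientRecord]) -> ConfusionCounts:
    """Count cells A/B/C/D over a cohort.

    Raises
    ------
    CohortError
        If the cohort is empty.
    """
    if len(cohort) == 0:
        raise CohortError("cannot tabulate an empty cohort")
    counts = {cell: 0 for cell in MortalityCell}
    for record in cohort:
        counts[classify_patient(record)] += 1
    return ConfusionCounts(
        a=counts[MortalityCell.A],
        b=counts[MortalityCell.B],
        c=counts[MortalityCell.C],
        d=counts[MortalityCell.D],
    )


def capture_metrics(counts: ConfusionCounts) -> tuple[float, float]:
    """Return ``(sensitivity, specificity)`` for the given cell counts."""
    return counts.sensitivity, counts.specificity


def cohort_from_cell_counts(
    a: int, b: int, c: int, d: int, arm: str = "cohort", death_day: float = 365.0
) -> list[PatientRecord]:
    """Build a minimal cohort realising the given confusion-cell counts.

    Classification depends only on the presence pattern of the two death
    dates, so published cell counts fully determine a cohort for any
    capture-arithmetic computation (sensitivity, specificity, degradation
    expectations).  All patients share an index at day 0; deaths fall on
    ``death_day``.
    """
    records: list[PatientRecord] = []
    specs = (
        ("A", a, death_day, death_day, death_day),
        ("B", b, death_day, None, death_day),
        ("C", c, None, death_day, death_day / 2),
        ("D", d, None, None, death_day),
    )
    for cell, count, ehr, gold, last in specs:
        for i in range(count):
            records.append(
                PatientRecord(
                    patient_id=f"{cell}{i:05d}",
                    index_date=0.0,
                    arm=arm,
                    ehr_death_date=ehr,
                    gold_death_date=gold,
                    last_activity_date=last,
                )
            )
    return records


# ---------------------------------------------------------------------------
# CSV round-trip

def _date_or_none(value) -> Optional[float]:
    if value is None or pd.isna(value):
        return None
    return float(value)


def cohort_to_frame(cohort: Sequence[PatientRecord], with_cell: bool = False) -> pd.DataFrame:
    """Convert records to a DataFrame (one row per patient)."""
    df = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in cohort],
            "index_date": [p.index_date for p in cohort],
            "arm": [p.arm for p in cohort],
            "ehr_death_date": [p.ehr_death_date for p in cohort],
            "gold_death_date": [p.gold_death_date for p in cohort],
            "last_activity_date": [p.last_activity_date for p in cohort],
        }
    )
    if with_cell:
        df["cell"] = [classify_patient(p).value for p in cohort]
    return df


def frame_to_cohort(df: pd.DataFrame) -> list[PatientRecord]:
    """Build validated records from a DataFrame with the cohort columns."""
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise CohortError(f"cohort table missing columns: {sorted(missing)}")
    return [
        PatientRecord(
            patient_id=str(row.patient_id),
            index_date=float(row.index_date),
            arm=str(row.arm),
            ehr_death_date=_date_or_none(row.ehr_death_date),
            gold_death_date=_date_or_none(row.gold_death_date),
            last_activity_date=float(row.last_activity_date),
        )
        for row in df.itertuples(index=False)
    ]


def write_cohort_csv(cohort: Sequence[PatientRecord], path, with_cell: bool = False) -> None:
    """Write a cohort CSV; absent death dates become empty fields.

    Integral day values are written without a decimal point so that the
    same seed yields a byte-identical file.
    """
    df = cohort_to_frame(cohort, with_cell=with_cell)
    for col in ("index_date", "ehr_death_date", "gold_death_date", "last_activity_date"):
        df[col] = df[col].map(_format_days)
    df.to_csv(path, index=False)


def _format_days(value) -> str:
    if value is None or pd.isna(value):
        return ""
    value = float(value)
    if value.is_integer():
        return str(int(value))
    return repr(value)


def read_cohort_csv(path) -> list[PatientRecord]:
    """Read a cohort CSV written by :func:`write_cohort_csv` (or compatible)."""
    df = pd.read_csv(path, dtype={"patient_id": str, "arm": str})
    return frame_to_cohort(df)


def counts_to_json(counts: ConfusionCounts, path) -> None:
    with open(path, "w") as fh:
        json.dump(counts.to_dict(), fh, indent=2)
        fh.write("\n")


def days_to_months(days: float) -> float:
    return days / DAYS_PER_MONTH


def months_to_days(months: float) -> float:
    return months * DAYS_PER_MONTH


def arms(cohort: Iterable[PatientRecord]) -> list[str]:
    """Distinct arm labels in first-appearance order."""
    seen: dict[str, None] = {}
    for p in cohort:
        seen.setdefault(p.arm, None)
    return list(seen)
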
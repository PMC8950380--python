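"""Domain types, validation and CSV readers/writers for cohorts and life tables.

The cohort CSV dialect is::

    id,age_dx,stage,her2,adherence,followup,exitus,year_dx

with ``stage`` in {I,II,III}, ``her2`` in {pos,neg}, ``adherence`` in
{yes,no,NA} and ``exitus`` in {died,survived}.  The life-table CSV has
columns ``age,year,rate`` where ``rate`` is an annual mortality hazard in
person-year^-1.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AGE_GROUPS",
    "STAGES",
    "HER2_LEVELS",
    "ADHERENCE_LEVELS",
    "EXITUS_LEVELS",
    "VARIABLE_LEVELS",
    "MISSING",
    "CohortError",
    "PatientRecord",
    "CohortFilterReport",
    "LifeTable",
    "age_group_of",
    "percentage",
    "round1",
    "read_cohort",
    "write_cohort",
    "read_lifetable",
    "write_lifetable",
    "cohort_to_frame",
    "frame_to_cohort",
]

AGE_GROUPS = ("<=49", "50-59", "60-74")
STAGES = ("I", "II", "III")
HER2_LEVELS = ("pos", "neg")
ADHERENCE_LEVELS = ("yes", "no")
EXITUS_LEVELS = ("died", "survived")
FOLLOWUP_LEVELS = tuple(range(1, 11))

#: Canonical level order of every categorical variable used by the
#: graphical-model engine (adherence excludes the missing code).
VARIABLE_LEVELS: dict[str, tuple] = {
    "age_group": AGE_GROUPS,
    "stage": STAGES,
    "her2": HER2_LEVELS,
    "adherence": ADHERENCE_LEVELS,
    "followup": FOLLOWUP_LEVELS,
    "exitus": EXITUS_LEVELS,
}

#: CSV code for a missing value.
MISSING = "NA"

AGE_MIN, AGE_MAX = 26, 74
FOLLOWUP_MAX = 10

_MISSING_CODES = {"", "NA", "na", "NaN", "nan", None}


class CohortError(ValueError):
    """Raised on malformed cohort or life-table input."""


def age_group_of(age_dx: int) -> str:
    """Map an exact age at diagnosis onto the three-level age group."""
    if age_dx <= 49:
        return AGE_GROUPS[0]
    if age_dx <= 59:
        return AGE_GROUPS[1]
    return AGE_GROUPS[2]


@dataclass(frozen=True, slots=True)
class PatientRecord:
    """One woman's diagnosis covariates plus discrete follow-up outcome.

    ``adherence`` is ``"yes"``, ``"no"`` or ``None`` (missing).  Follow-up is
    recorded in whole years 1..10; ``exitus == "survived"`` means the record
    is censored at ``followup``.
    """

    id: str
    age_dx: int
    stage: str
    her2: str
    adherence: str | None
    followup: int
    exitus: str
    year_dx: int

    @property
    def age_group(self) -> str:
        return age_group_of(self.age_dx)

    def validate(self) -> None:
        if not AGE_MIN <= self.age_dx <= AGE_MAX:
            raise CohortError(
                f"record {self.id!r}: age_dx {self.age_dx} outside [{AGE_MIN}, {AGE_MAX}]"
            )
        if self.stage not in STAGES:
            raise CohortError(f"record {self.id!r}: unknown stage code {self.stage!r}")
        if self.her2 not in HER2_LEVELS:
            raise CohortError(f"record {self.id!r}: unknown her2 code {self.her2!r}")
        if self.adherence is not None and self.adherence not in ADHERENCE_LEVELS:
            raise CohortError(
                f"record {self.id!r}: unknown adherence code {self.adherence!r}"
            )
        if not 1 <= self.followup <= FOLLOWUP_MAX:
            raise CohortError(
                f"record {self.id!r}: followup {self.followup} outside 1..{FOLLOWUP_MAX}"
            )
        if self.exitus not in EXITUS_LEVELS:
            raise CohortError(f"record {self.id!r}: unknown exitus code {self.exitus!r}")


#: Exclusion rules in the order they are applied; a record failing several
#: rules is counted once, under the first matching rule.
EXCLUSION_RULES = ("receptor", "stage", "followup")


@dataclass
class CohortFilterReport:
    """Counts of records dropped per exclusion rule plus the surviving N."""

    dropped: dict[str, int] = field(
        default_factory=lambda: {rule: 0 for rule in EXCLUSION_RULES}
    )
    kept: int = 0

    @property
    def total(self) -> int:
        return self.kept + sum(self.dropped.values())


class LifeTable:
    """General-population annual mortality hazard keyed by (age, calendar year).

    Lookups above ``max_age`` (or below ``min_age``) clamp to the nearest
    covered age; a missing (age, year) pair inside the covered range is an
    error.
    """

    def __init__(self, rates: Mapping[tuple[int, int], float]):
        if not rates:
            raise CohortError("life table is empty")
        for (age, year), rate in rates.items():
            if rate < 0:
                raise CohortError(f"negative rate {rate} at (age={age}, year={year})")
        self._rates = dict(rates)
        self.min_age = min(a for a, _ in self._rates)
        self.max_age = max(a for a, _ in self._rates)
        self.years = sorted({y for _, y in self._rates})

    def lookup(self, age: int, year: int) -> float:
        age = min(max(int(age), self.min_age), self.max_age)
        try:
            return self._rates[(age, int(year))]
        except KeyError:
            raise CohortError(f"life table has no entry for (age={age}, year={year})")

    def __contains__(self, key: tuple[int, int]) -> bool:
        return key in self._rates

    def validate_coverage(self, min_age: int, max_age: int, years: Iterable[int]) -> None:
        """Check complete (age x year) coverage; raise listing the first gap."""
        for year in years:
            for age in range(min_age, max_age + 1):
                if (age, year) not in self._rates:
                    raise CohortError(
                        f"life table missing entry (age={age}, year={year})"
                    )

    def items(self):
        return self._rates.items()


def percentage(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator, rounded to 1 decimal, half away from zero."""
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    frac = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def round1(x: float) -> float:
    """Round to one decimal, half away from zero (reporting convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


_COHORT_COLUMNS = ("id", "age_dx", "stage", "her2", "adherence", "followup", "exitus", "year_dx")


def _is_missing(value) -> bool:
    return value in _MISSING_CODES or (isinstance(value, float) and value != value)


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    followup_rule_index: int = 2,
) -> tuple[list[PatientRecord], CohortFilterReport]:
    """Read a cohort CSV, applying the eligibility exclusion rules in order.

    Exclusion rules (first match counts): ``receptor`` -- missing receptor
    (her2) status; ``stage`` -- missing stage or a stage code outside I-III
    (e.g. IV); ``followup`` -- unretrievable follow-up.  The position of the
    follow-up rule is configurable via ``followup_rule_index`` because the
    source ordering of that rule is not fixed by the data dictionary.

    ``schema`` optionally maps canonical column names to the file's column
    names.  Returns the validated records and a :class:`CohortFilterReport`.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise CohortError(f"cannot read cohort file {path}: {exc}") from exc
    if schema:
        frame = frame.rename(columns={v: k for k, v in schema.items()})
    missing_cols = [c for c in _COHORT_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise CohortError(f"cohort file {path} lacks columns {missing_cols}")

    rules = [r for r in EXCLUSION_RULES if r != "followup"]
    rules.insert(min(followup_rule_index, len(rules)), "followup")

    report = CohortFilterReport(dropped={rule: 0 for rule in rules})
    records: list[PatientRecord] = []
    for _, row in frame.iterrows():
        rid = row["id"]
        excluded = False
        for rule in rules:
            if rule == "receptor" and _is_missing(row["her2"]):
                excluded = True
            elif rule == "stage" and (
                _is_missing(row["stage"]) or row["stage"] == "IV"
            ):
                excluded = True
            elif rule == "followup" and _is_missing(row["followup"]):
                excluded = True
            if excluded:
                report.dropped[rule] += 1
                break
        if excluded:
            continue
        try:
            followup = int(row["followup"])
            age_dx = int(row["age_dx"])
            year_dx = int(row["year_dx"])
        except ValueError as exc:
            raise CohortError(f"record {rid!r}: non-integer field ({exc})") from exc
        record = PatientRecord(
            id=str(rid),
            age_dx=age_dx,
            stage=row["stage"],
            her2=row["her2"],
            adherence=None if _is_missing(row["adherence"]) else row["adherence"],
            followup=followup,
            exitus=row["exitus"],
            year_dx=year_dx,
        )
        record.validate()
        records.append(record)
        report.kept += 1
    return records, report


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write records in the canonical CSV dialect (deterministic byte layout)."""
    path = Path(path)
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(_COHORT_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.id,
                    rec.age_dx,
                    rec.stage,
                    rec.her2,
                    MISSING if rec.adherence is None else rec.adherence,
                    rec.followup,
                    rec.exitus,
                    rec.year_dx,
                ]
            )


def read_lifetable(path: str | Path) -> LifeTable:
    """Read a life-table CSV with columns age, year, rate."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except OSError as exc:
        raise CohortError(f"cannot read life table {path}: {exc}") from exc
    for col in ("age", "year", "rate"):
        if col not in frame.columns:
            raise CohortError(f"life table {path} lacks column {col!r}")
    keys = list(zip(frame["age"].astype(int), frame["year"].astype(int)))
    if len(set(keys)) != len(keys):
        dupes = frame[frame.duplicated(subset=["age", "year"], keep=False)]
        raise CohortError(
            f"duplicate (age, year) keys in {path}: {dupes[['age', 'year']].values[:3].tolist()}"
        )
    return LifeTable(dict(zip(keys, frame["rate"].astype(float))))


def write_lifetable(table: LifeTable, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["age", "year", "rate"])
        for (age, year), rate in sorted(table.items()):
            writer.writerow([age, year, repr(float(rate))])


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Tabular view of a cohort (adherence missing encoded as None)."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "age_dx": [r.age_dx for r in records],
            "age_group": [r.age_group for r in records],
            "stage": [r.stage for r in records],
            "her2": [r.her2 for r in records],
            "adherence": [r.adherence for r in records],
            "followup": [r.followup for r in records],
            "exitus": [r.exitus for r in records],
            "year_dx": [r.year_dx for r in records],
        }
    )


def frame_to_cohort(frame: pd.DataFrame) -> list[PatientRecord]:
    """Inverse of :func:`cohort_to_frame`; validates every record."""
    records = []
    for _, row in frame.iterrows():
        adherence = row["adherence"]
        rec = PatientRecord(
            id=str(row["id"]),
            age_dx=int(row["age_dx"]),
            stage=row["stage"],
            her2=row["her2"],
            adherence=None if _is_missing(adherence) else adherence,
            followup=int(row["followup"]),
            exitus=row["exitus"],
            year_dx=int(row["year_dx"]),
        )
        rec.validate()
        records.append(rec)
    return records
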
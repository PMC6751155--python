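"""Canonical on-disk tables: pharmacy transcripts, subjects, outcomes, features, partitions.

One CSV file per table, fixed headers, ISO-8601 dates, decimal point only.
Writers are bit-stable given identical records, and ``write`` then ``read``
round-trips every table exactly (floats are written with ``repr`` so the
shortest round-tripping decimal representation is used).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, fields
from datetime import date
from enum import Enum
from pathlib import Path

from .errors import ConsistencyError, FormatError, RowError

log = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


class DrugClass(str, Enum):
    STIMULANT_IR = "stimulant_ir"
    STIMULANT_XR = "stimulant_xr"
    DEXAMPHETAMINE = "dexamphetamine"
    NON_STIMULANT_ANTIPSYCHOTIC = "non_stimulant_antipsychotic"
    NON_STIMULANT_ATOMOXETINE = "non_stimulant_atomoxetine"
    NON_STIMULANT_ANXIOLYTIC = "non_stimulant_anxiolytic"
    NON_STIMULANT_ANTIDEPRESSANT = "non_stimulant_antidepressant"


#: Classes whose dispensed dose contributes to the stimulant trajectory.
STIMULANT_CLASSES = frozenset(
    {DrugClass.STIMULANT_IR, DrugClass.STIMULANT_XR, DrugClass.DEXAMPHETAMINE}
)


class GroupFlag(str, Enum):
    ADHD_TREATED = "adhd_treated"
    ADHD_NAIVE = "adhd_naive"
    CONTROL = "control"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


@dataclass(frozen=True)
class PrescriptionRecord:
    """One dispensing event from a pharmacy transcript."""

    subject_id: str
    dispense_date: date
    drug_class: DrugClass
    unit_strength: float  # mg per unit
    units_dispensed: float
    daily_units: float

    def __post_init__(self):
        if self.unit_strength <= 0:
            raise ConsistencyError(f"{self.subject_id}: unit_strength must be > 0")
        if self.units_dispensed <= 0:
            raise ConsistencyError(f"{self.subject_id}: units_dispensed must be > 0")
        if self.daily_units <= 0:
            raise ConsistencyError(f"{self.subject_id}: daily_units must be > 0")
        if self.supply_days < 1:
            raise ConsistencyError(
                f"{self.subject_id}: dispense on {self.dispense_date} covers "
                f"{self.supply_days:.2f} days (< 1)"
            )

    @property
    def daily_dose(self) -> float:
        """Dose in mg/day while this supply is consumed."""
        return self.unit_strength * self.daily_units

    @property
    def supply_days(self) -> float:
        return self.units_dispensed / self.daily_units


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    family_id: str
    birth_date: date
    followup_date: date
    group_flag: GroupFlag
    baseline_age: float
    hyperactive_symptoms: int
    inattentive_symptoms: int
    cd: bool
    odd: bool
    iq: float
    ses: float
    sex: Sex

    def __post_init__(self):
        if self.followup_date <= self.birth_date:
            raise ConsistencyError(f"{self.subject_id}: follow-up date not after birth")
        if self.age_at_followup < 12:
            raise ConsistencyError(
                f"{self.subject_id}: age at follow-up {self.age_at_followup:.1f} < 12"
            )
        if not (0 <= self.hyperactive_symptoms <= 9):
            raise ConsistencyError(f"{self.subject_id}: hyperactive_symptoms outside 0-9")
        if not (0 <= self.inattentive_symptoms <= 9):
            raise ConsistencyError(f"{self.subject_id}: inattentive_symptoms outside 0-9")

    @property
    def age_at_followup(self) -> float:
        """Exact age in years (day count / 365.25)."""
        return (self.followup_date - self.birth_date).days / DAYS_PER_YEAR


@dataclass(frozen=True)
class OutcomeRecord:
    subject_id: str
    sud: bool
    daily_smoking: bool
    nicotine_dependence: bool
    age_first_substance_use: float | None = None
    age_first_nicotine_use: float | None = None

    def __post_init__(self):
        if self.sud and self.age_first_substance_use is None:
            raise ConsistencyError(
                f"{self.subject_id}: sud=true but age_first_substance_use absent"
            )
        if (self.daily_smoking or self.nicotine_dependence) and (
            self.age_first_nicotine_use is None
        ):
            raise ConsistencyError(
                f"{self.subject_id}: smoking/ND event but age_first_nicotine_use absent"
            )


PRESCRIPTION_HEADER = [
    "subject_id",
    "dispense_date",
    "drug_class",
    "unit_strength_mg",
    "units_dispensed",
    "daily_units",
]
SUBJECT_HEADER = [
    "subject_id",
    "family_id",
    "birth_date",
    "followup_date",
    "group_flag",
    "baseline_age",
    "hyperactive_symptoms",
    "inattentive_symptoms",
    "cd",
    "odd",
    "iq",
    "ses",
    "sex",
]
OUTCOME_HEADER = [
    "subject_id",
    "sud",
    "daily_smoking",
    "nicotine_dependence",
    "age_first_substance_use",
    "age_first_nicotine_use",
]


def _parse_date(s: str, line: int) -> date:
    try:
        return date.fromisoformat(s)
    except ValueError as exc:
        raise RowError(f"unparseable ISO date {s!r}", line) from exc


def _parse_float(s: str, name: str, line: int) -> float:
    try:
        return float(s)
    except ValueError as exc:
        raise RowError(f"unparseable {name} {s!r}", line) from exc


def _parse_bool(s: str, name: str, line: int) -> bool:
    if s == "true":
        return True
    if s == "false":
        return False
    raise RowError(f"{name} must be 'true' or 'false', got {s!r}", line)


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, Enum):
        return v.value
    if isinstance(v, date):
        return v.isoformat()
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _open_rows(path, expected_header):
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"{path}: empty file, expected header {expected_header}")
    header = rows[0]
    missing = [c for c in expected_header if c not in header]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if header != expected_header:
        raise FormatError(f"{path}: header {header} != expected {expected_header}")
    return rows[1:]


def read_prescriptions(path) -> list[PrescriptionRecord]:
    """Read a transcript file, sorted by (subject_id, dispense_date)."""
    out = []
    for i, row in enumerate(_open_rows(path, PRESCRIPTION_HEADER), start=2):
        if len(row) != len(PRESCRIPTION_HEADER):
            raise RowError(f"expected {len(PRESCRIPTION_HEADER)} fields, got {len(row)}", i)
        sid, d, cls, strength, units, daily = row
        try:
            drug = DrugClass(cls)
        except ValueError as exc:
            raise RowError(f"unknown drug_class {cls!r}", i) from exc
        try:
            rec = PrescriptionRecord(
                subject_id=sid,
                dispense_date=_parse_date(d, i),
                drug_class=drug,
                unit_strength=_parse_float(strength, "unit_strength_mg", i),
                units_dispensed=_parse_float(units, "units_dispensed", i),
                daily_units=_parse_float(daily, "daily_units", i),
            )
        except ConsistencyError as exc:
            raise RowError(str(exc), i) from exc
        out.append(rec)
    out.sort(key=lambda r: (r.subject_id, r.dispense_date))
    return out


def read_subjects(path) -> list[SubjectRecord]:
    out = []
    for i, row in enumerate(_open_rows(path, SUBJECT_HEADER), start=2):
        if len(row) != len(SUBJECT_HEADER):
            raise RowError(f"expected {len(SUBJECT_HEADER)} fields, got {len(row)}", i)
        try:
            rec = SubjectRecord(
                subject_id=row[0],
                family_id=row[1],
                birth_date=_parse_date(row[2], i),
                followup_date=_parse_date(row[3], i),
                group_flag=GroupFlag(row[4]),
                baseline_age=_parse_float(row[5], "baseline_age", i),
                hyperactive_symptoms=int(row[6]),
                inattentive_symptoms=int(row[7]),
                cd=_parse_bool(row[8], "cd", i),
                odd=_parse_bool(row[9], "odd", i),
                iq=_parse_float(row[10], "iq", i),
                ses=_parse_float(row[11], "ses", i),
                sex=Sex(row[12]),
            )
        except (ValueError, ConsistencyError) as exc:
            raise RowError(str(exc), i) from exc
        out.append(rec)
    out.sort(key=lambda r: r.subject_id)
    return out


def read_outcomes(path) -> list[OutcomeRecord]:
    out = []
    for i, row in enumerate(_open_rows(path, OUTCOME_HEADER), start=2):
        if len(row) != len(OUTCOME_HEADER):
            raise RowError(f"expected {len(OUTCOME_HEADER)} fields, got {len(row)}", i)
        try:
            rec = OutcomeRecord(
                subject_id=row[0],
                sud=_parse_bool(row[1], "sud", i),
                daily_smoking=_parse_bool(row[2], "daily_smoking", i),
                nicotine_dependence=_parse_bool(row[3], "nicotine_dependence", i),
                age_first_substance_use=(
                    _parse_float(row[4], "age_first_substance_use", i) if row[4] else None
                ),
                age_first_nicotine_use=(
                    _parse_float(row[5], "age_first_nicotine_use", i) if row[5] else None
                ),
            )
        except ConsistencyError as exc:
            raise RowError(str(exc), i) from exc
        out.append(rec)
    out.sort(key=lambda r: r.subject_id)
    return out


_WRITERS = {
    PrescriptionRecord: (
        PRESCRIPTION_HEADER,
        lambda r: [
            r.subject_id,
            r.dispense_date,
            r.drug_class,
            r.unit_strength,
            r.units_dispensed,
            r.daily_units,
        ],
    ),
    SubjectRecord: (SUBJECT_HEADER, lambda r: [getattr(r, f.name) for f in fields(SubjectRecord)]),
    OutcomeRecord: (OUTCOME_HEADER, lambda r: [getattr(r, f.name) for f in fields(OutcomeRecord)]),
}


def write_table(records, path, record_type=None) -> None:
    """Write homogeneous records to ``path`` in the canonical dialect.

    ``record_type`` is required only for writing an empty table.
    """
    if record_type is None:
        if not records:
            raise ValueError("record_type required for an empty table")
        record_type = type(records[0])
    header, as_row = _WRITERS[record_type]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(header)
        for rec in records:
            if not isinstance(rec, record_type):
                raise ValueError(f"mixed record types: {type(rec)} vs {record_type}")
            w.writerow([_fmt(v) for v in as_row(rec)])


def warn_untreated_with_prescriptions(prescriptions, subjects) -> list[str]:
    """Flag control / naive subjects that appear in the transcript.

    Policy: warn and keep the records; the trajectory stage decides what a
    stimulant dispense means for group membership. Returns the flagged ids.
    """
    untreated = {
        s.subject_id for s in subjects if s.group_flag is not GroupFlag.ADHD_TREATED
    }
    stim_by_subject = {
        r.subject_id for r in prescriptions if r.drug_class in STIMULANT_CLASSES
    }
    flagged = sorted(untreated & stim_by_subject)
    for sid in flagged:
        log.warning(
            "subject %s is flagged %s but has stimulant dispenses in the transcript; "
            "records kept",
            sid,
            next(s.group_flag.value for s in subjects if s.subject_id == sid),
        )
    return flagged
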
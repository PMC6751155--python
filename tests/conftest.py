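import sys
from datetime import date, timedelta
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make helpers importable

from stimtraj.io import (
    DrugClass,
    GroupFlag,
    PrescriptionRecord,
    Sex,
    SubjectRecord,
)

BIRTH = date(1992, 9, 1)


def make_subject(
    sid="s1",
    family="f1",
    birth=BIRTH,
    followup_age_years=16.0,
    group=GroupFlag.ADHD_TREATED,
    **kw,
):
    fu = birth + timedelta(days=round(followup_age_years * 365.25))
    defaults = dict(
        baseline_age=followup_age_years - 4.0,
        hyperactive_symptoms=7,
        inattentive_symptoms=8,
        cd=False,
        odd=False,
        iq=100.0,
        ses=12.0,
        sex=Sex.MALE,
    )
    defaults.update(kw)
    return SubjectRecord(sid, family, birth, fu, group, **defaults)


def dispense(
    sid="s1",
    day=0,
    birth=BIRTH,
    drug=DrugClass.STIMULANT_IR,
    dose=10.0,
    days_supply=30,
    strength=None,
):
    """A dispense of `dose` mg/day for `days_supply` days starting at `day`."""
    if strength is None:
        strength = 10.0 if dose % 10 == 0 else (5.0 if dose % 5 == 0 else dose)
    daily_units = dose / strength
    return PrescriptionRecord(
        subject_id=sid,
        dispense_date=birth + timedelta(days=day),
        drug_class=drug,
        unit_strength=strength,
        units_dispensed=daily_units * days_supply,
        daily_units=daily_units,
    )


def constant_dose_records(sid="s1", birth=BIRTH, start_age=8.0, years=2.0, dose=20.0):
    """30-day supplies giving `dose` mg/day for every whole day in the span."""
    import math

    start = round(start_age * 365.25)
    n = math.ceil(years * 365.25 - 1e-9)
    recs, d = [], 0
    while d < n:
        chunk = min(30, n - d)
        recs.append(dispense(sid, start + d, birth, dose=dose, days_supply=chunk))
        d += chunk
    return recs


@pytest.fixture
def treated_subject():
    return make_subject()


@pytest.fixture
def constant_subject_pair(treated_subject):
    """The hand-built constant-dose case: 20 mg/day, ages 8-10, follow-up 16."""
    return constant_dose_records(), treated_subject
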
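"""Daily stimulant-dose trajectories reconstructed from dispensing records.

A trajectory covers every day from birth to follow-up (inclusive), 0-based
from the birth date, with half-open supply intervals: the day of dispense is
included, and a supply of ``units_dispensed / daily_units`` days covers that
many whole days at ``unit_strength * daily_units`` mg/day.

Overlap rule: a newer stimulant dispense of the *same* drug class supersedes
the remaining supply of the previous one (no stockpiling — this mirrors
titration practice, where a changed prescription replaces the old one);
dispenses of *different* classes (e.g. IR + XR methylphenidate) run
concurrently and their doses sum. Only stimulant classes contribute dose;
non-stimulant dispenses contribute to the coverage flags only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import DataError, UndefinedFeaturesError
from .io import DAYS_PER_YEAR, STIMULANT_CLASSES, PrescriptionRecord, SubjectRecord

#: Month length in days used for monthly binning, anchored at birth.
DAYS_PER_MONTH = DAYS_PER_YEAR / 12  # 30.4375


@dataclass
class DoseTrajectory:
    """Per-day stimulant dose in mg/day from birth to follow-up (inclusive)."""

    subject_id: str
    dose: np.ndarray  # mg/day, length n_days
    covered: np.ndarray  # bool, day under an active dispense supply
    birth_index_of_followup: int  # day index of the follow-up date

    @property
    def n_days(self) -> int:
        return len(self.dose)

    @property
    def age_at_followup(self) -> float:
        return self.birth_index_of_followup / DAYS_PER_YEAR

    def is_all_zero(self) -> bool:
        return not np.any(self.dose > 0)


@dataclass(frozen=True)
class RawFeatures:
    """Features read off the raw (unsmoothed) daily trajectory."""

    start_age: float  # years, first non-zero day
    stop_age: float  # years, last non-zero day + 1 day (supply exhaustion)
    total_dose: float  # mg, sum of the daily series
    rel_total_dose: float  # mg per eligible-year


class MonthlySeries(NamedTuple):
    """Average daily dose per consecutive 30.4375-day month, anchored at birth."""

    ages: np.ndarray  # month midpoint ages, years
    doses: np.ndarray  # mean daily dose over the month, mg/day
    day_counts: np.ndarray  # days of the trajectory falling in each month
    window_start_age: float  # age at the start of the first treated month
    window_end_age: float  # age at the end of the last treated month


def build_daily_trajectory(
    records: list[PrescriptionRecord], subject: SubjectRecord
) -> DoseTrajectory:
    """Reconstruct the per-day dose series for one subject."""
    n_days = (subject.followup_date - subject.birth_date).days + 1
    dose = np.zeros(n_days)
    covered = np.zeros(n_days, dtype=bool)

    # Active interval per drug class: [start_day, end_day) at a constant dose.
    intervals: list[list] = []  # [start, end, dose, drug_class, is_stimulant]
    last_by_class: dict = {}
    for rec in sorted(records, key=lambda r: r.dispense_date):
        if rec.subject_id != subject.subject_id:
            raise DataError(
                f"record for {rec.subject_id} passed with subject {subject.subject_id}"
            )
        day = (rec.dispense_date - subject.birth_date).days
        if day < 0:
            raise DataError(
                f"{subject.subject_id}: dispense on {rec.dispense_date} before birth"
            )
        if rec.dispense_date > subject.followup_date:
            raise DataError(
                f"{subject.subject_id}: dispense on {rec.dispense_date} after follow-up"
            )
        supply = max(1, int(round(rec.supply_days)))
        iv = [day, day + supply, rec.daily_dose, rec.drug_class,
              rec.drug_class in STIMULANT_CLASSES]
        prev = last_by_class.get(rec.drug_class)
        if prev is not None and prev[1] > day:
            prev[1] = day  # supersede remaining supply of the same class
        intervals.append(iv)
        last_by_class[rec.drug_class] = iv

    for start, end, d, _cls, is_stim in intervals:
        end = min(end, n_days)
        if end <= start:
            continue
        covered[start:end] = True
        if is_stim:
            dose[start:end] += d

    return DoseTrajectory(
        subject_id=subject.subject_id,
        dose=dose,
        covered=covered,
        birth_index_of_followup=n_days - 1,
    )


def raw_features(traj: DoseTrajectory, start_age_offset: float) -> RawFeatures:
    """Raw-trajectory features for a treated subject.

    ``rel_total_dose`` divides the cumulative dose by the *eligible* years,
    i.e. age at follow-up minus the earliest start age in the sample (the
    offset), so that it is corrected for the age span over which treatment
    was possible at all.
    """
    nz = np.flatnonzero(traj.dose > 0)
    if nz.size == 0:
        raise UndefinedFeaturesError(
            f"{traj.subject_id}: all-zero trajectory has no treatment features"
        )
    age_fu = traj.age_at_followup
    if age_fu <= start_age_offset:
        raise DataError(
            f"{traj.subject_id}: follow-up age {age_fu:.2f} <= offset {start_age_offset}"
        )
    start_age = nz[0] / DAYS_PER_YEAR
    stop_age = (nz[-1] + 1) / DAYS_PER_YEAR
    total = float(traj.dose.sum())
    return RawFeatures(
        start_age=start_age,
        stop_age=stop_age,
        total_dose=total,
        rel_total_dose=total / (age_fu - start_age_offset),
    )


def monthly_average(traj: DoseTrajectory) -> MonthlySeries:
    """Average monthly daily dose over the treated window.

    Months are consecutive 30.4375-day bins from birth; each bin value is the
    arithmetic mean of the daily doses falling in it. For treated subjects the
    series is restricted to [first treated month, last treated month]; for an
    all-zero trajectory the series is empty.
    """
    nz = np.flatnonzero(traj.dose > 0)
    if nz.size == 0:
        empty = np.empty(0)
        return MonthlySeries(empty, empty, np.empty(0, dtype=int), 0.0, 0.0)
    month_index = (np.arange(traj.n_days) / DAYS_PER_MONTH).astype(int)
    first_m = int(nz[0] / DAYS_PER_MONTH)
    last_m = int(nz[-1] / DAYS_PER_MONTH)
    months = np.arange(first_m, last_m + 1)
    counts = np.bincount(month_index, minlength=last_m + 1)[first_m : last_m + 1]
    sums = np.bincount(month_index, weights=traj.dose, minlength=last_m + 1)[
        first_m : last_m + 1
    ]
    if np.any(counts == 0):  # trajectory shorter than the binned window
        raise DataError(f"{traj.subject_id}: empty month inside the treated window")
    ages = (months + 0.5) * DAYS_PER_MONTH / DAYS_PER_YEAR
    return MonthlySeries(
        ages=ages,
        doses=sums / counts,
        day_counts=counts,
        window_start_age=first_m * DAYS_PER_MONTH / DAYS_PER_YEAR,
        window_end_age=(last_m + 1) * DAYS_PER_MONTH / DAYS_PER_YEAR,
    )


def export_long(trajectories: list[DoseTrajectory], path) -> None:
    """Debug export: long-format CSV (subject_id, day_index, dose_mg)."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["subject_id", "day_index", "dose_mg"])
        for traj in trajectories:
            for d in np.flatnonzero(traj.dose > 0):
                w.writerow([traj.subject_id, int(d), repr(float(traj.dose[d]))])
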
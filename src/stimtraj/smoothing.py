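"""Per-subject smoothing of monthly average daily dose, and the six-feature profile.

The smoother is a generalized additive model in its simplest useful form: a
Gaussian-error penalized cubic B-spline of dose on age, with a second-order
difference penalty on the spline coefficients and the smoothing parameter
chosen by generalized cross-validation (GCV) over a log-spaced grid. The
penalty null space contains constant and linear trends, so noiseless constant
or linear dose histories are reproduced exactly at any smoothing level.

Smoothing exists to suppress the high-frequency dose changes inherent to
day-resolution pharmacy reconstruction; three of the six profile features
(relative duration, maximum dose, dose variability) are read off the fitted
curve, the other three (start age, relative total dose, stop age) off the raw
trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .errors import DataError
from .io import DAYS_PER_YEAR, SubjectRecord
from .trajectory import DoseTrajectory, MonthlySeries, monthly_average, raw_features

#: Canonical feature order used by every downstream stage.
FEATURE_NAMES = (
    "start_age",
    "rel_duration",
    "rel_total_dose",
    "max_dose",
    "dose_variability",
    "stop_age",
)

SPLINE_DEGREE = 3
LAMBDA_GRID = np.logspace(-4, 6, 21)
MIN_POINTS_FOR_SPLINE = 4


@dataclass
class SmoothedTrajectory:
    """A fitted dose curve evaluated on a daily grid over the treated window."""

    ages: np.ndarray  # daily evaluation grid (years), strictly increasing
    fitted: np.ndarray  # fitted dose, clamped >= 0 (mg/day)
    lam: float  # selected smoothing parameter (nan for the fallback path)
    basis_dim: int  # number of B-spline basis functions (0 for fallback)
    window: tuple[float, float]  # [first, last] age of the fit window
    fallback: bool  # True when < MIN_POINTS_FOR_SPLINE months were available


@dataclass(frozen=True)
class TreatmentProfile:
    """The six-feature stimulant treatment history of one subject."""

    subject_id: str
    start_age: float  # years (raw)
    rel_duration: float  # GAM duration / (age - start_age_offset), dimensionless
    rel_total_dose: float  # mg per eligible-year (raw)
    max_dose: float  # mg/day (GAM)
    dose_variability: float  # mg/day, population SD of the fitted curve (GAM)
    stop_age: float  # years (raw)
    fallback: bool = False

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_NAMES])


def _basis_dim(n_months: int) -> int:
    return min(10, max(4, math.ceil(n_months / 4)))


def _design(x: np.ndarray, lo: float, hi: float, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Clamped uniform cubic B-spline design matrix with k basis functions."""
    n_interior = k - SPLINE_DEGREE - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate(
        [np.repeat(lo, SPLINE_DEGREE + 1), interior, np.repeat(hi, SPLINE_DEGREE + 1)]
    )
    B = BSpline.design_matrix(np.clip(x, lo, hi), knots, SPLINE_DEGREE).toarray()
    return B, knots


def fit_gam(monthly: MonthlySeries) -> SmoothedTrajectory:
    """Fit the penalized spline to one subject's monthly dose series.

    With fewer than four monthly points a spline fit is ill-posed; those
    subjects fall back to their raw monthly means held constant over each
    month, and the result is flagged so downstream summaries can report how
    often the fallback was taken.
    """
    x, y = monthly.ages, monthly.doses
    if x.size == 0:
        raise DataError("empty monthly series: nothing to smooth")
    if x.size > 1 and np.any(np.diff(x) <= 0):
        raise DataError("monthly age grid must be strictly increasing")
    lo, hi = monthly.window_start_age, monthly.window_end_age
    n_grid = int(round((hi - lo) * DAYS_PER_YEAR))
    grid = lo + (np.arange(n_grid) + 0.5) / DAYS_PER_YEAR

    if x.size < MIN_POINTS_FOR_SPLINE:
        # Piecewise-constant fallback: each day takes its month's mean dose.
        month_edges = np.linspace(lo, hi, x.size + 1)
        idx = np.clip(np.searchsorted(month_edges, grid, side="right") - 1, 0, x.size - 1)
        fitted = np.maximum(y[idx], 0.0)
        return SmoothedTrajectory(
            ages=grid, fitted=fitted, lam=float("nan"), basis_dim=0,
            window=(lo, hi), fallback=True,
        )

    k = _basis_dim(x.size)
    B, knots = _design(x, lo, hi, k)
    D = np.diff(np.eye(k), n=2, axis=0)  # second-order difference penalty
    P = D.T @ D
    BtB = B.T @ B
    Bty = B.T @ y

    best = None
    for lam in LAMBDA_GRID:
        A = BtB + lam * P
        try:
            coef = np.linalg.solve(A, Bty)
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            continue
        resid = y - B @ coef
        rss = float(resid @ resid)
        edf = float(np.sum((B @ Ainv) * B))  # tr(H)
        denom = max(x.size - edf, 1e-8)
        gcv = x.size * rss / denom**2
        if best is None or gcv < best[0] - 1e-12:
            best = (gcv, lam, coef)
    if best is None:
        raise DataError("spline system singular at every smoothing level")
    _, lam, coef = best

    spline = BSpline(knots, coef, SPLINE_DEGREE, extrapolate=False)
    fitted = spline(np.clip(grid, lo, hi))
    fitted = np.nan_to_num(fitted, nan=0.0)
    return SmoothedTrajectory(
        ages=grid,
        fitted=np.maximum(fitted, 0.0),
        lam=float(lam),
        basis_dim=k,
        window=(lo, hi),
        fallback=False,
    )


def gam_features(
    sm: SmoothedTrajectory,
    age_at_followup: float,
    start_age_offset: float,
    duration_threshold: float = 1.0,
) -> tuple[float, float, float]:
    """(rel_duration, max_dose, dose_variability) from a fitted curve.

    Duration is the measure, in years, of grid days whose fitted dose is at
    least ``duration_threshold`` (default 1 mg/day — below any prescribable
    dose, so it separates "on treatment" from numerically-zero tails of the
    smooth). Variability is the population SD of the fitted curve over the
    fit window.
    """
    if age_at_followup <= start_age_offset:
        raise DataError(
            f"age at follow-up {age_at_followup:.2f} <= offset {start_age_offset}"
        )
    duration = float(np.count_nonzero(sm.fitted >= duration_threshold)) / DAYS_PER_YEAR
    rel_duration = duration / (age_at_followup - start_age_offset)
    max_dose = float(sm.fitted.max(initial=0.0))
    dose_variability = float(sm.fitted.std()) if sm.fitted.size else 0.0
    return rel_duration, max_dose, dose_variability


def build_profiles(
    trajectories: list[DoseTrajectory],
    subjects: list[SubjectRecord],
    start_age_offset: float | None = None,
    duration_threshold: float = 1.0,
) -> tuple[list[TreatmentProfile], list[str]]:
    """Assemble six-feature profiles for treated subjects.

    Subjects whose trajectory is all-zero are routed to the stimulant-naive
    list instead of failing. When ``start_age_offset`` is None it is computed
    as the earliest start age among treated subjects in this sample (the
    within-sample definition of "age of possible use").
    """
    by_id = {s.subject_id: s for s in subjects}
    treated = [t for t in trajectories if not t.is_all_zero()]
    naive_ids = [t.subject_id for t in trajectories if t.is_all_zero()]

    if start_age_offset is None:
        if not treated:
            raise DataError("no treated subjects: cannot derive start_age_offset")
        start_age_offset = min(
            float(np.flatnonzero(t.dose > 0)[0]) / DAYS_PER_YEAR for t in treated
        )

    profiles = []
    for traj in treated:
        try:
            subj = by_id[traj.subject_id]
            raw = raw_features(traj, start_age_offset)
            sm = fit_gam(monthly_average(traj))
            rel_dur, max_dose, var = gam_features(
                sm, subj.age_at_followup, start_age_offset, duration_threshold
            )
        except KeyError as exc:
            raise DataError(f"trajectory {traj.subject_id} has no subject record") from exc
        except DataError as exc:
            raise DataError(f"subject {traj.subject_id}: {exc}") from exc
        profiles.append(
            TreatmentProfile(
                subject_id=traj.subject_id,
                start_age=raw.start_age,
                rel_duration=rel_dur,
                rel_total_dose=raw.rel_total_dose,
                max_dose=max_dose,
                dose_variability=var,
                stop_age=raw.stop_age,
                fallback=sm.fallback,
            )
        )
    return profiles, naive_ids


def profiles_to_matrix(profiles: list[TreatmentProfile]) -> np.ndarray:
    """Stack profiles into a (subjects x 6) feature matrix in canonical order."""
    return np.array([p.as_vector() for p in profiles])


def write_features(profiles: list[TreatmentProfile], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["subject_id", *FEATURE_NAMES, "fallback_flag"])
        for p in profiles:
            w.writerow(
                [p.subject_id]
                + [repr(float(getattr(p, f))) for f in FEATURE_NAMES]
                + ["true" if p.fallback else "false"]
            )


def read_features(path) -> list[TreatmentProfile]:
    import csv

    from .errors import FormatError

    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    expected = ["subject_id", *FEATURE_NAMES, "fallback_flag"]
    if not rows or rows[0] != expected:
        raise FormatError(f"{path}: expected header {expected}")
    out = []
    for row in rows[1:]:
        vals = dict(zip(FEATURE_NAMES, map(float, row[1:7])))
        out.append(
            TreatmentProfile(subject_id=row[0], fallback=row[7] == "true", **vals)
        )
    return out
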
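"""Synthetic cohort generator with planted treatment subgroups and event hazards.

The generator emulates the data structure the analysis assumes: three treated
subgroups whose start age, stop age and plateau dose are drawn at the study's
printed subgroup moments, plus a stimulant-naive ADHD group and controls;
sibling pairs sharing a family id; and event ages from a Weibull
proportional-hazards model with group-specific log hazard ratios and a shared
gamma frailty per family, censored at the follow-up age.

Dose paths are piecewise-constant at day resolution: an optional titration
ramp, Poisson-timed stepwise dose changes, and Bernoulli-per-year treatment
gaps of at least 60 days; doses are quantized to 5 mg steps (minimum 2.5 mg,
reflecting available unit strengths) and dispensed as 30-day supplies, so the
trajectory stage can reconstruct the planted path exactly.

Every draw flows from the single config seed; identical config + seed gives
byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from datetime import date, timedelta

import numpy as np

from .errors import ConfigError, GenerationError
from .io import (
    DAYS_PER_YEAR,
    DrugClass,
    GroupFlag,
    OutcomeRecord,
    PrescriptionRecord,
    Sex,
    SubjectRecord,
)

#: Fixed follow-up calendar date; birth dates are derived from drawn ages.
FOLLOWUP_DATE = date(2008, 9, 1)

GROUP_NAMES = (
    "early_and_intense",
    "early_and_moderate",
    "late_and_moderate",
    "stimulant_naive",
    "control",
)

#: Printed subgroup feature means (start age, rel. duration, cumulative dose in
#: mg per eligible-year, maximum dose, dose variability, stop age) used to seed
#: both the dose-path specs and the planted-profile sampler.
TABLE1_FEATURE_MEANS = {
    "late_and_moderate": (11.47, 0.73, 5700.0, 23.93, 98.93, 15.73),
    "early_and_moderate": (7.73, 0.87, 8540.0, 22.62, 70.49, 15.31),
    "early_and_intense": (7.09, 0.87, 18510.0, 53.35, 334.08, 14.66),
}

# per-group covariate moments: (male p, iq mean, iq sd, hyper mean, hyper sd,
# inatt mean, inatt sd, odd p, cd p, ses mean, ses sd)
_COVARIATE_MOMENTS = {
    "stimulant_naive": (0.759, 98.4, 15.22, 7.08, 2.23, 8.04, 1.24, 0.302, 0.189, 12.22, 2.75),
    "late_and_moderate": (0.739, 99.53, 12.96, 7.83, 1.40, 7.90, 1.69, 0.333, 0.227, 11.20, 1.94),
    "early_and_moderate": (0.824, 96.97, 13.01, 7.88, 1.47, 8.20, 0.98, 0.500, 0.149, 11.26, 2.39),
    "early_and_intense": (0.864, 100.95, 13.65, 8.25, 1.15, 8.07, 1.07, 0.432, 0.185, 11.32, 2.04),
    "control": (0.402, 105.56, 9.52, 1.0, 1.0, 1.0, 1.0, 0.05, 0.02, 12.58, 2.66),
}


@dataclass(frozen=True)
class SubgroupSpec:
    """Generating parameters of one treated subgroup's dose paths."""

    name: str
    n: int
    start_age_mean: float
    start_age_sd: float
    stop_age_mean: float
    stop_age_sd: float
    plateau_dose_mean: float  # mg/day
    plateau_dose_sd: float
    dose_change_rate: float  # expected dose changes per treated year
    dose_change_sd: float  # mg, SD of a step change
    gap_prob: float  # probability of a >=60-day gap per treated year

    def __post_init__(self):
        if self.n < 0:
            raise ConfigError(f"{self.name}: n must be >= 0")
        for f_ in ("start_age_sd", "stop_age_sd", "plateau_dose_sd", "dose_change_sd"):
            if getattr(self, f_) < 0:
                raise ConfigError(f"{self.name}: {f_} must be >= 0")
        if self.stop_age_mean <= self.start_age_mean:
            raise ConfigError(f"{self.name}: stop_age_mean must exceed start_age_mean")
        if not 0 <= self.gap_prob <= 1:
            raise ConfigError(f"{self.name}: gap_prob must be a probability")


@dataclass(frozen=True)
class OutcomeSpec:
    """Weibull proportional-hazards generating model for one outcome domain."""

    baseline_weibull_shape: float
    baseline_weibull_scale: float  # years
    log_hr_by_group: dict[str, float]
    frailty_variance: float = 0.0  # gamma frailty variance, shared within family

    def __post_init__(self):
        if self.baseline_weibull_shape <= 0 or self.baseline_weibull_scale <= 0:
            raise ConfigError("Weibull shape and scale must be > 0")
        if self.frailty_variance < 0:
            raise ConfigError("frailty_variance must be >= 0")


@dataclass
class CohortConfig:
    subgroup_specs: list[SubgroupSpec]
    outcome_specs: dict[str, OutcomeSpec]
    n_naive: int = 58
    n_controls: int = 219
    sibling_fraction: float = 0.4
    followup_age_mean: float = 16.0
    followup_age_sd: float = 2.3
    followup_age_min: float = 12.0
    seed: int = 0

    def __post_init__(self):
        if self.n_naive < 0 or self.n_controls < 0:
            raise ConfigError("counts must be >= 0")
        if not 0 <= self.sibling_fraction <= 1:
            raise ConfigError("sibling_fraction must be a probability")
        if self.seed is None:
            raise ConfigError("seed is mandatory")

    def to_dict(self) -> dict:
        return asdict(self)


def default_subgroup_specs() -> list[SubgroupSpec]:
    """The three treated subgroups at the study's printed moments."""
    return [
        SubgroupSpec(
            name="early_and_intense", n=103,
            start_age_mean=7.09, start_age_sd=1.53,
            stop_age_mean=14.66, stop_age_sd=2.34,
            plateau_dose_mean=53.35, plateau_dose_sd=17.89,
            dose_change_rate=2.0, dose_change_sd=10.0, gap_prob=0.2,
        ),
        SubgroupSpec(
            name="early_and_moderate", n=51,
            start_age_mean=7.73, start_age_sd=1.32,
            stop_age_mean=15.31, stop_age_sd=2.42,
            plateau_dose_mean=22.62, plateau_dose_sd=9.81,
            dose_change_rate=0.5, dose_change_sd=5.0, gap_prob=0.1,
        ),
        SubgroupSpec(
            name="late_and_moderate", n=91,
            start_age_mean=11.47, start_age_sd=2.39,
            stop_age_mean=15.73, stop_age_sd=2.58,
            plateau_dose_mean=23.93, plateau_dose_sd=14.61,
            dose_change_rate=0.5, dose_change_sd=5.0, gap_prob=0.3,
        ),
    ]


def default_outcome_specs() -> dict[str, OutcomeSpec]:
    """Per-domain Weibull PH models anchored to the printed hazard-ratio pattern.

    Reference hazard is the early-and-intense subgroup; log-HRs reproduce the
    within-ADHD contrasts (SUD: late 2.70, early-moderate 2.66, naive 3.57;
    ND: 2.78 / 1.04 / 3.45; daily smoking: 0.68 / 0.75 / 0.81). Baseline
    shape/scale put the per-group event fractions at follow-up near the
    printed percentages.
    """
    return {
        "sud": OutcomeSpec(
            baseline_weibull_shape=6.0, baseline_weibull_scale=24.0,
            log_hr_by_group={
                "early_and_intense": 0.0,
                "early_and_moderate": math.log(2.66),
                "late_and_moderate": math.log(2.70),
                "stimulant_naive": math.log(3.57),
                "control": 0.0,
            },
            frailty_variance=0.5,
        ),
        "daily_smoking": OutcomeSpec(
            baseline_weibull_shape=5.0, baseline_weibull_scale=19.0,
            log_hr_by_group={
                "early_and_intense": 0.0,
                "early_and_moderate": math.log(0.75),
                "late_and_moderate": math.log(0.68),
                "stimulant_naive": math.log(0.81),
                "control": math.log(0.5),
            },
            frailty_variance=0.5,
        ),
        "nicotine_dependence": OutcomeSpec(
            baseline_weibull_shape=8.0, baseline_weibull_scale=22.0,
            log_hr_by_group={
                "early_and_intense": 0.0,
                "early_and_moderate": math.log(1.04),
                "late_and_moderate": math.log(2.78),
                "stimulant_naive": math.log(3.45),
                "control": math.log(0.28),
            },
            frailty_variance=0.5,
        ),
    }


def default_config(seed: int) -> CohortConfig:
    return CohortConfig(
        subgroup_specs=default_subgroup_specs(),
        outcome_specs=default_outcome_specs(),
        seed=seed,
    )


def planted_group(subject_id: str) -> str:
    """Recover the planted group name encoded in a synthetic subject id."""
    return subject_id.rsplit("-", 1)[0]


def _quantize(dose: float) -> float:
    """Quantize to 5 mg steps, minimum 2.5 mg."""
    return max(2.5, round(dose / 5.0) * 5.0)


@dataclass
class DosePath:
    """Planted day-resolution dose schedule for one treated subject."""

    start_age: float  # years at the first treated day
    stop_age: float  # years at supply exhaustion
    daily: np.ndarray  # mg/day for each day from the start day

    def segments(self) -> list[tuple[int, int, float]]:
        """(start_day, end_day, dose) runs of constant dose, gaps included."""
        out = []
        if self.daily.size == 0:
            return out
        change = np.flatnonzero(np.diff(self.daily)) + 1
        bounds = np.concatenate([[0], change, [self.daily.size]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            out.append((int(a), int(b), float(self.daily[a])))
        return out


def simulate_dose_path(spec: SubgroupSpec, rng: np.random.Generator) -> DosePath:
    """Draw one piecewise-constant dose schedule from a subgroup spec.

    Start and stop ages are redrawn (up to 1000 attempts) until the treated
    window is at least 90 days. When ``dose_change_rate`` is zero the path is
    the constant plateau dose (no titration ramp), so the no-change limit is
    exactly flat.
    """
    for _ in range(1000):
        start = rng.normal(spec.start_age_mean, spec.start_age_sd)
        stop = rng.normal(spec.stop_age_mean, spec.stop_age_sd)
        if start >= 2.0 and stop - start >= 90 / DAYS_PER_YEAR:
            break
    else:
        raise GenerationError(f"{spec.name}: could not draw stop > start in 1000 tries")

    n_days = int(round((stop - start) * DAYS_PER_YEAR))
    plateau = _quantize(rng.normal(spec.plateau_dose_mean, spec.plateau_dose_sd))
    daily = np.full(n_days, plateau)

    if spec.dose_change_rate > 0:
        # titration ramp: two 30-day steps at half and three-quarters plateau
        if n_days > 90 and plateau > 5:
            daily[:30] = _quantize(plateau * 0.5)
            daily[30:60] = _quantize(plateau * 0.75)
        years = n_days / DAYS_PER_YEAR
        n_changes = rng.poisson(spec.dose_change_rate * years)
        change_days = np.sort(rng.integers(60 if n_days > 90 else 0, n_days,
                                           size=n_changes))
        current = plateau
        for cd in change_days:
            current = _quantize(current + rng.normal(0.0, spec.dose_change_sd))
            daily[cd:] = current

    # treatment gaps: one Bernoulli trial per treated year
    n_years = max(1, int(math.ceil(n_days / DAYS_PER_YEAR - 1e-9)))
    for y in range(n_years):
        if rng.random() < spec.gap_prob:
            gap_len = int(rng.integers(60, 121))
            y0 = int(round(y * DAYS_PER_YEAR))
            y1 = min(int(round((y + 1) * DAYS_PER_YEAR)), n_days)
            if y1 - y0 <= gap_len:
                g0 = y0
            else:
                g0 = int(rng.integers(y0, y1 - gap_len))
            daily[g0 : min(g0 + gap_len, n_days)] = 0.0

    # trim leading/trailing zero days introduced by gaps at the edges
    nz = np.flatnonzero(daily > 0)
    if nz.size == 0:
        daily = np.full(max(n_days, 30), plateau)  # degenerate: gap ate everything
        nz = np.arange(daily.size)
    daily = daily[nz[0] : nz[-1] + 1]
    start = start + nz[0] / DAYS_PER_YEAR
    return DosePath(start_age=start, stop_age=start + daily.size / DAYS_PER_YEAR, daily=daily)


def _dispenses_for_path(
    sid: str, birth: date, followup: date, path: DosePath, drug: DrugClass
) -> list[PrescriptionRecord]:
    """Emit 30-day supplies reproducing the planted path exactly."""
    out = []
    start_day = int(round(path.start_age * DAYS_PER_YEAR))
    followup_day = (followup - birth).days
    for a, b, dose in path.segments():
        if dose <= 0:
            continue
        strength = 10.0 if dose % 10 == 0 else (5.0 if dose % 5 == 0 else 2.5)
        daily_units = dose / strength
        day = a
        while day < b:
            chunk = min(30, b - day)
            abs_day = start_day + day
            if abs_day > followup_day:
                break
            out.append(
                PrescriptionRecord(
                    subject_id=sid,
                    dispense_date=birth + timedelta(days=abs_day),
                    drug_class=drug,
                    unit_strength=strength,
                    units_dispensed=daily_units * chunk,
                    daily_units=daily_units,
                )
            )
            day += chunk
    return out


def _draw_followup_age(cfg: CohortConfig, rng) -> float:
    for _ in range(1000):
        a = rng.normal(cfg.followup_age_mean, cfg.followup_age_sd)
        if a >= cfg.followup_age_min:
            return a
    raise GenerationError("could not draw follow-up age above the minimum")


def _make_subject(sid: str, family: str, group: str, flag: GroupFlag,
                  followup_age: float, rng) -> SubjectRecord:
    (p_male, iq_m, iq_s, hy_m, hy_s, ia_m, ia_s, p_odd, p_cd, ses_m, ses_s) = (
        _COVARIATE_MOMENTS[group]
    )
    birth = FOLLOWUP_DATE - timedelta(days=int(round(followup_age * DAYS_PER_YEAR)))
    baseline_age = max(1.0, followup_age - max(1.0, rng.normal(4.2, 0.7)))
    return SubjectRecord(
        subject_id=sid,
        family_id=family,
        birth_date=birth,
        followup_date=FOLLOWUP_DATE,
        group_flag=flag,
        baseline_age=baseline_age,
        hyperactive_symptoms=int(np.clip(round(rng.normal(hy_m, hy_s)), 0, 9)),
        inattentive_symptoms=int(np.clip(round(rng.normal(ia_m, ia_s)), 0, 9)),
        cd=bool(rng.random() < p_cd),
        odd=bool(rng.random() < p_odd),
        iq=float(max(70.0, rng.normal(iq_m, iq_s))),
        ses=float(max(0.0, rng.normal(ses_m, ses_s))),
        sex=Sex.MALE if rng.random() < p_male else Sex.FEMALE,
    )


def _assign_families(ids: list[str], fraction: float, prefix: str, rng) -> dict[str, str]:
    """Pair ``fraction`` of the subjects into two-child families."""
    n = len(ids)
    n_paired = int(round(fraction * n))
    n_pairs = n_paired // 2
    perm = rng.permutation(n)
    fam: dict[str, str] = {}
    fam_counter = 0
    for k in range(n_pairs):
        fid = f"{prefix}F{fam_counter:04d}"
        fam_counter += 1
        fam[ids[perm[2 * k]]] = fid
        fam[ids[perm[2 * k + 1]]] = fid
    for i in perm[2 * n_pairs :]:
        fam[ids[i]] = f"{prefix}F{fam_counter:04d}"
        fam_counter += 1
    return fam


def simulate_event_ages(
    subjects: list[SubjectRecord],
    outcome_specs: dict[str, OutcomeSpec],
    group_labels: dict[str, str],
    rng: np.random.Generator,
) -> list[OutcomeRecord]:
    """Draw event ages per domain from the Weibull PH model with gamma frailty.

    The event time for domain d is T = scale * (E / m)^(1/shape) with
    E ~ Exp(1) and multiplier m = exp(log_hr_group) * frailty; the event is
    recorded iff T is below the follow-up age. Daily smoking and nicotine
    dependence share the age-at-first-nicotine-use field: it is the earliest
    of the domain event times that occurred.
    """
    missing = [s.subject_id for s in subjects if s.subject_id not in group_labels]
    if missing:
        raise GenerationError(f"unlabeled subject(s): {missing[:5]}")
    families = sorted({s.family_id for s in subjects})
    frailty: dict[tuple[str, str], float] = {}
    for domain in sorted(outcome_specs):
        v = outcome_specs[domain].frailty_variance
        for fam in families:
            frailty[(domain, fam)] = rng.gamma(1.0 / v, v) if v > 0 else 1.0

    out = []
    for s in subjects:
        grp = group_labels[s.subject_id]
        ages: dict[str, float | None] = {}
        for domain in sorted(outcome_specs):
            spec = outcome_specs[domain]
            try:
                loghr = spec.log_hr_by_group[grp]
            except KeyError:
                raise GenerationError(f"no log HR for group {grp!r} in {domain}") from None
            m = math.exp(loghr) * frailty[(domain, s.family_id)]
            t = spec.baseline_weibull_scale * (rng.exponential(1.0) / m) ** (
                1.0 / spec.baseline_weibull_shape
            )
            ages[domain] = t if t < s.age_at_followup else None
        nic = [ages[d] for d in ("daily_smoking", "nicotine_dependence") if ages.get(d)]
        out.append(
            OutcomeRecord(
                subject_id=s.subject_id,
                sud=ages.get("sud") is not None,
                daily_smoking=ages.get("daily_smoking") is not None,
                nicotine_dependence=ages.get("nicotine_dependence") is not None,
                age_first_substance_use=ages.get("sud"),
                age_first_nicotine_use=min(nic) if nic else None,
            )
        )
    return out


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[PrescriptionRecord], list[SubjectRecord], list[OutcomeRecord]]:
    """Generate the three tables for one synthetic cohort."""
    rng = np.random.default_rng(config.seed)

    adhd_ids = [
        f"{spec.name}-{i:03d}" for spec in config.subgroup_specs for i in range(spec.n)
    ] + [f"stimulant_naive-{i:03d}" for i in range(config.n_naive)]
    control_ids = [f"control-{i:03d}" for i in range(config.n_controls)]
    if not adhd_ids and not control_ids:
        return [], [], []

    fam = _assign_families(adhd_ids, config.sibling_fraction, "A", rng)
    fam.update(_assign_families(control_ids, config.sibling_fraction, "C", rng))

    subjects: list[SubjectRecord] = []
    prescriptions: list[PrescriptionRecord] = []
    group_labels: dict[str, str] = {}

    for spec in config.subgroup_specs:
        for i in range(spec.n):
            sid = f"{spec.name}-{i:03d}"
            fu_age = _draw_followup_age(config, rng)
            for _ in range(1000):
                path = simulate_dose_path(spec, rng)
                if path.start_age < fu_age - 1 / DAYS_PER_YEAR:
                    break
            else:
                raise GenerationError(
                    f"{sid}: could not place treatment before follow-up in 1000 tries"
                )
            subj = _make_subject(sid, fam[sid], spec.name, GroupFlag.ADHD_TREATED,
                                 fu_age, rng)
            drug = (
                DrugClass.DEXAMPHETAMINE if rng.random() < 0.086 else DrugClass.STIMULANT_IR
            )
            recs = _dispenses_for_path(sid, subj.birth_date, subj.followup_date, path, drug)
            if not recs:  # path starts within a day of follow-up; force one dispense
                raise GenerationError(f"{sid}: planted path produced no dispense")
            prescriptions.extend(recs)
            if rng.random() < 0.25:  # non-stimulant co-medication (sensitivity covariate)
                mid = subj.birth_date + timedelta(
                    days=(subj.followup_date - subj.birth_date).days // 2
                )
                prescriptions.append(
                    PrescriptionRecord(
                        subject_id=sid,
                        dispense_date=mid,
                        drug_class=DrugClass.NON_STIMULANT_ANTIPSYCHOTIC,
                        unit_strength=1.0,
                        units_dispensed=30.0,
                        daily_units=1.0,
                    )
                )
            subjects.append(subj)
            group_labels[sid] = spec.name

    for sid in (f"stimulant_naive-{i:03d}" for i in range(config.n_naive)):
        fu_age = _draw_followup_age(config, rng)
        subjects.append(
            _make_subject(sid, fam[sid], "stimulant_naive", GroupFlag.ADHD_NAIVE, fu_age, rng)
        )
        group_labels[sid] = "stimulant_naive"

    for sid in control_ids:
        fu_age = _draw_followup_age(config, rng)
        subjects.append(
            _make_subject(sid, fam[sid], "control", GroupFlag.CONTROL, fu_age, rng)
        )
        group_labels[sid] = "control"

    outcomes = simulate_event_ages(subjects, config.outcome_specs, group_labels, rng)

    prescriptions.sort(key=lambda r: (r.subject_id, r.dispense_date))
    subjects.sort(key=lambda s: s.subject_id)
    outcomes.sort(key=lambda o: o.subject_id)
    return prescriptions, subjects, outcomes


def sample_planted_profiles(
    n_per_group: int = 50,
    seed: int = 0,
    sd_scale: float = 0.1,
):
    """Draw six-feature profiles directly at the printed subgroup means.

    Within-group SDs are ``sd_scale`` times the between-group feature range,
    so the default places subgroup centroids roughly 10 within-SD apart —
    a planted-partition fixture for community-recovery checks, bypassing the
    transcript stages. Returns (profiles, labels: subject_id -> group name).
    """
    from .smoothing import TreatmentProfile

    rng = np.random.default_rng(seed)
    M = np.array([TABLE1_FEATURE_MEANS[g] for g in
                  ("late_and_moderate", "early_and_moderate", "early_and_intense")])
    sds = np.maximum((M.max(axis=0) - M.min(axis=0)) * sd_scale, 1e-6)
    profiles, labels = [], {}
    for gi, grp in enumerate(("late_and_moderate", "early_and_moderate", "early_and_intense")):
        draws = rng.normal(M[gi], sds, size=(n_per_group, 6))
        draws[:, 1] = np.clip(draws[:, 1], 0.0, 1.0)  # rel_duration is a fraction
        draws[:, 2:5] = np.maximum(draws[:, 2:5], 0.0)
        for i, row in enumerate(draws):
            sid = f"{grp}-{i:03d}"
            profiles.append(
                TreatmentProfile(
                    subject_id=sid,
                    start_age=row[0], rel_duration=row[1], rel_total_dose=row[2],
                    max_dose=row[3], dose_variability=row[4], stop_age=row[5],
                )
            )
            labels[sid] = grp
    return profiles, labels
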
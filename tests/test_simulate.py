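"""Synthetic cohort generator: determinism, planted moments, PH structure."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from stimtraj.io import (
    DAYS_PER_YEAR,
    STIMULANT_CLASSES,
    GroupFlag,
    PrescriptionRecord,
    write_table,
)
from stimtraj.simulate import (
    CohortConfig,
    OutcomeSpec,
    SubgroupSpec,
    default_config,
    default_outcome_specs,
    default_subgroup_specs,
    planted_group,
    sample_planted_profiles,
    simulate_cohort,
    simulate_dose_path,
    simulate_event_ages,
)


def small_config(seed=0, n=15):
    specs = [dataclasses.replace(s, n=n) for s in default_subgroup_specs()]
    return CohortConfig(
        subgroup_specs=specs, outcome_specs=default_outcome_specs(),
        n_naive=6, n_controls=8, seed=seed,
    )


def test_empty_config_gives_empty_tables():
    specs = [dataclasses.replace(s, n=0) for s in default_subgroup_specs()]
    cfg = CohortConfig(subgroup_specs=specs, outcome_specs=default_outcome_specs(),
                       n_naive=0, n_controls=0, seed=1)
    assert simulate_cohort(cfg) == ([], [], [])


def test_same_seed_byte_identical_files(tmp_path):
    for run in ("a", "b"):
        pre, subj, out = simulate_cohort(small_config(seed=11))
        write_table(pre, tmp_path / f"{run}_pre.csv", PrescriptionRecord)
        write_table(subj, tmp_path / f"{run}_subj.csv")
        write_table(out, tmp_path / f"{run}_out.csv")
    for t in ("pre", "subj", "out"):
        assert (tmp_path / f"a_{t}.csv").read_bytes() == (tmp_path / f"b_{t}.csv").read_bytes()


def test_different_seeds_differ():
    _, s1, _ = simulate_cohort(small_config(seed=1))
    _, s2, _ = simulate_cohort(small_config(seed=2))
    assert s1 != s2


def test_treated_have_stimulant_dispenses_and_others_do_not():
    pre, subj, _ = simulate_cohort(small_config(seed=3))
    with_rx = {r.subject_id for r in pre}
    for s in subj:
        if s.group_flag is GroupFlag.ADHD_TREATED:
            assert s.subject_id in with_rx
        elif s.group_flag is GroupFlag.CONTROL:
            assert s.subject_id not in with_rx


def test_sibling_fraction_creates_pairwise_families():
    cfg = small_config(seed=4, n=40)
    _, subj, _ = simulate_cohort(cfg)
    adhd = [s for s in subj if s.group_flag is not GroupFlag.CONTROL]
    fam_sizes = {}
    for s in adhd:
        fam_sizes[s.family_id] = fam_sizes.get(s.family_id, 0) + 1
    paired = sum(v for v in fam_sizes.values() if v == 2)
    assert paired == pytest.approx(cfg.sibling_fraction * len(adhd), abs=2)
    assert max(fam_sizes.values()) <= 2


def test_mean_start_ages_match_truncation_oracle():
    """Generator subgroup start-age means vs a direct rejection-sampling oracle."""
    cfg = small_config(seed=5, n=200)
    cfg = dataclasses.replace(cfg, n_naive=0, n_controls=0)
    pre, subj, _ = simulate_cohort(cfg)
    birth = {s.subject_id: s.birth_date for s in subj}
    by_subject = {}
    for r in pre:
        if r.drug_class not in STIMULANT_CLASSES:
            continue
        d = (r.dispense_date - birth[r.subject_id]).days
        by_subject.setdefault(r.subject_id, []).append(d)
    starts = {sid: min(ds) / DAYS_PER_YEAR for sid, ds in by_subject.items()}
    for spec in cfg.subgroup_specs:
        got = np.mean([a for sid, a in starts.items() if planted_group(sid) == spec.name])
        # oracle: the generator's two-stage scheme — follow-up age drawn once
        # per subject, then (start, stop) rejection-drawn until admissible
        rng = np.random.default_rng(12345)
        acc = []
        while len(acc) < 20000:
            fu = rng.normal(16.0, 2.3)
            if fu < 12:
                continue
            while True:
                start = rng.normal(spec.start_age_mean, spec.start_age_sd)
                stop = rng.normal(spec.stop_age_mean, spec.stop_age_sd)
                if (
                    start >= 2.0
                    and stop - start >= 90 / DAYS_PER_YEAR
                    and start < fu - 1 / DAYS_PER_YEAR
                ):
                    break
            acc.append(start)
        assert got == pytest.approx(np.mean(acc), abs=0.2)


class TestDosePath:
    def test_no_change_limit_is_constant(self):
        spec = SubgroupSpec("x", 1, 8.0, 0.0, 12.0, 0.0, 30.0, 0.0, 0.0, 0.0, 0.0)
        path = simulate_dose_path(spec, np.random.default_rng(0))
        assert np.ptp(path.daily) == 0.0
        assert path.daily[0] == 30.0

    def test_certain_gap_in_one_year_treatment(self):
        spec = SubgroupSpec("x", 1, 10.0, 0.0, 11.0, 0.0, 20.0, 0.0, 0.0, 0.0, 1.0)
        path = simulate_dose_path(spec, np.random.default_rng(1))
        zeros = path.daily == 0
        # longest zero run must be >= 60 days
        runs = np.diff(np.flatnonzero(np.diff(np.r_[0, zeros.view(np.int8), 0])))
        assert zeros.any() and runs.max() >= 60

    def test_step_sd_matches_generating_parameter(self):
        spec = SubgroupSpec("x", 1, 10.0, 0.0, 12.0, 0.0, 50.0, 0.0, 2.0, 10.0, 0.0)
        rng = np.random.default_rng(2)
        diffs = []
        for _ in range(500):
            path = simulate_dose_path(spec, rng)
            seg = [d for _, _, d in path.segments() if d > 0]
            diffs.extend(np.diff(seg))
        sd = np.std(diffs)
        # step ~ N(0, 10) plus 5 mg quantization noise
        assert 9.0 <= sd <= 11.0

    def test_doses_quantized_to_available_strengths(self):
        spec = SubgroupSpec("x", 1, 8.0, 1.0, 14.0, 1.0, 33.0, 12.0, 2.0, 8.0, 0.3)
        rng = np.random.default_rng(3)
        for _ in range(20):
            path = simulate_dose_path(spec, rng)
            nz = path.daily[path.daily > 0]
            assert np.all((nz == 2.5) | (np.mod(nz, 5.0) == 0))
            assert nz.min() >= 2.5


class TestEventAges:
    def _subjects(self, n, followup_age=16.0, families=None):
        from conftest import make_subject

        return [
            make_subject(
                f"g-{i:04d}",
                family=f"f{families[i] if families is not None else i}",
                followup_age_years=followup_age,
                group=GroupFlag.ADHD_TREATED,
            )
            for i in range(n)
        ]

    def test_null_model_matches_weibull_survivor(self):
        """Pooled Kaplan-Meier under no group effect vs the closed-form survivor."""
        lifelines = pytest.importorskip("lifelines")
        shape, scale = 4.0, 20.0
        spec = OutcomeSpec(shape, scale, {"g": 0.0}, frailty_variance=0.0)
        subjects = self._subjects(2000, followup_age=18.0)
        rng = np.random.default_rng(0)
        outs = simulate_event_ages(
            subjects, {"sud": spec}, {s.subject_id: "g" for s in subjects}, rng
        )
        times = [o.age_first_substance_use if o.sud else 18.0 for o in outs]
        events = [int(o.sud) for o in outs]
        km = lifelines.KaplanMeierFitter().fit(times, events)
        for t in (10.0, 14.0, 17.0):
            s_true = np.exp(-((t / scale) ** shape))
            s_km = float(km.survival_function_at_times(t).iloc[0])
            assert s_km == pytest.approx(s_true, abs=0.03)

    def test_infinite_scale_censors_everyone(self):
        spec = OutcomeSpec(6.0, 1e9, {"g": 0.0})
        subjects = self._subjects(50)
        outs = simulate_event_ages(
            subjects, {"sud": spec}, {s.subject_id: "g" for s in subjects},
            np.random.default_rng(1),
        )
        assert not any(o.sud for o in outs)

    def test_log_cumulative_hazards_parallel_without_frailty(self):
        """PH structure: the two groups' log cumulative hazards differ by log HR."""
        lifelines = pytest.importorskip("lifelines")
        spec = OutcomeSpec(6.0, 18.0, {"a": 0.0, "b": np.log(2.7)})
        subjects = self._subjects(4000, followup_age=18.0)
        labels = {s.subject_id: ("a" if i < 2000 else "b") for i, s in enumerate(subjects)}
        outs = simulate_event_ages(subjects, {"sud": spec}, labels, np.random.default_rng(2))
        diffs = []
        for t in (12.0, 14.0, 16.0):
            by = {}
            for grp in ("a", "b"):
                times = [
                    o.age_first_substance_use if o.sud else 18.0
                    for o in outs
                    if labels[o.subject_id] == grp
                ]
                events = [int(o.sud) for o in outs if labels[o.subject_id] == grp]
                na = lifelines.NelsonAalenFitter().fit(times, events)
                by[grp] = float(na.cumulative_hazard_at_times(t).iloc[0])
            diffs.append(np.log(by["b"]) - np.log(by["a"]))
        assert np.allclose(diffs, np.log(2.7), atol=0.15)

    def test_frailty_induces_positive_sibling_dependence(self):
        spec = OutcomeSpec(6.0, 18.0, {"g": 0.0}, frailty_variance=0.8)
        n = 2000
        families = np.repeat(np.arange(n // 2), 2)
        subjects = self._subjects(n, followup_age=60.0, families=families)
        outs = simulate_event_ages(
            subjects, {"sud": spec}, {s.subject_id: "g" for s in subjects},
            np.random.default_rng(3),
        )
        ages = np.array([o.age_first_substance_use for o in outs], float)
        tau = stats.kendalltau(ages[0::2], ages[1::2]).statistic
        assert tau > 0.15  # theoretical tau = v/(v+2) ~= 0.29

    def test_hr_recovery_through_cox(self):
        from stimtraj.survival import fit_cox, make_survival_dataset

        spec = OutcomeSpec(6.0, 18.0, {"a": 0.0, "b": np.log(2.7)})
        subjects = self._subjects(1000)
        labels = {s.subject_id: ("a" if i < 500 else "b") for i, s in enumerate(subjects)}
        outs = simulate_event_ages(subjects, {"sud": spec}, labels, np.random.default_rng(4))
        df = make_survival_dataset(subjects, outs, labels, "sud")
        fit = fit_cox(df, reference_group="a")
        se = fit.robust_se()[0]
        assert fit.beta[0] == pytest.approx(np.log(2.7), abs=3 * se)


def test_planted_profiles_are_well_separated():
    profiles, labels = sample_planted_profiles(50, seed=0)
    from stimtraj.community import standardize

    z = standardize(profiles)
    groups = np.array([labels[p.subject_id] for p in profiles])
    cents = {g: z[groups == g].mean(axis=0) for g in set(groups)}
    within = np.mean([z[groups == g].std(axis=0).mean() for g in set(groups)])
    names = sorted(cents)
    min_sep = min(
        np.linalg.norm(cents[a] - cents[b]) / within
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    )
    assert min_sep >= 4.0


def test_default_config_reflects_study_group_sizes():
    cfg = default_config(seed=0)
    sizes = {s.name: s.n for s in cfg.subgroup_specs}
    assert sizes == {"early_and_intense": 103, "early_and_moderate": 51,
                     "late_and_moderate": 91}
    assert cfg.n_naive == 58 and cfg.n_controls == 219
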
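"""Cox model: partial likelihood, robust variance, contrasts, incidence, matching."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_subject
from helpers import cox_grid_oracle
from stimtraj.errors import ConsistencyError, DataError, DegenerateDataError
from stimtraj.io import OutcomeRecord
from stimtraj.survival import (
    CoxFit,
    cumulative_incidence,
    fit_cox,
    make_survival_dataset,
    match_groups,
    non_stimulant_users,
    pairwise_hazard_ratios,
    wald_group_test,
)


def small_frame(times, events, groups, families=None):
    n = len(times)
    return pd.DataFrame(
        {
            "time": times,
            "event": events,
            "group": groups,
            "family_id": families if families is not None else np.arange(n),
        }
    )


def two_group_weibull(n, hr, seed, scale=18.0, shape=6.0, family_pairs=False, frailty=0.0):
    rng = np.random.default_rng(seed)
    if family_pairs:
        fam = np.repeat(np.arange(n // 2), 2)
        grp = np.repeat(rng.integers(0, 2, n // 2), 2)
    else:
        fam = np.arange(n)
        grp = np.repeat([0, 1], n // 2)
    mult = np.exp(np.log(hr) * grp)
    if frailty > 0:
        mult = mult * np.repeat(rng.gamma(1 / frailty, frailty, n // 2), 2) if family_pairs \
            else mult * rng.gamma(1 / frailty, frailty, n)
    t = scale * (rng.exponential(1, n) / mult) ** (1 / shape)
    fu = np.maximum(rng.normal(16, 2.3, n), 12)
    return small_frame(
        np.minimum(t, fu), (t < fu).astype(int),
        np.where(grp == 1, "g1", "g0"), fam,
    )


class TestMakeSurvivalDataset:
    def setup_method(self):
        self.subjects = [make_subject(f"s{i}", followup_age_years=16.8) for i in range(3)]
        self.groups = {f"s{i}": "a" for i in range(3)}

    def test_cases_and_censoring_rule(self):
        outcomes = [
            OutcomeRecord("s0", True, False, False, 14.2, None),
            OutcomeRecord("s1", False, False, False, None, None),
            OutcomeRecord("s2", False, True, False, None, 13.0),
        ]
        df = make_survival_dataset(self.subjects, outcomes, self.groups, "sud")
        assert df.loc[df.subject_id == "s0", "time"].item() == 14.2
        assert df.loc[df.subject_id == "s0", "event"].item() == 1
        s1 = df.loc[df.subject_id == "s1"]
        assert s1["event"].item() == 0
        assert s1["time"].item() == pytest.approx(16.8, abs=0.01)
        # s2 is a smoking case but a SUD non-case
        assert df.loc[df.subject_id == "s2", "event"].item() == 0

    def test_smoking_domains_share_nicotine_age(self):
        outcomes = [
            OutcomeRecord("s0", False, True, True, None, 13.5),
            OutcomeRecord("s1", False, False, False, None, None),
            OutcomeRecord("s2", False, False, False, None, None),
        ]
        for domain in ("daily_smoking", "nicotine_dependence"):
            df = make_survival_dataset(self.subjects, outcomes, self.groups, domain)
            assert df.loc[df.subject_id == "s0", "time"].item() == 13.5

    def test_case_age_at_or_after_followup_rejected(self):
        outcomes = [
            OutcomeRecord("s0", True, False, False, 17.5, None),
            OutcomeRecord("s1", False, False, False, None, None),
            OutcomeRecord("s2", False, False, False, None, None),
        ]
        with pytest.raises(ConsistencyError, match="s0"):
            make_survival_dataset(self.subjects, outcomes, self.groups, "sud")

    def test_empty_cohort_gives_empty_frame(self):
        assert make_survival_dataset([], [], {}, "sud").empty

    def test_unknown_domain_rejected(self):
        with pytest.raises(DataError):
            make_survival_dataset([], [], {}, "mortality")


class TestFitCox:
    def test_beta_matches_grid_search_oracle(self):
        times = [2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        events = [1, 1, 0, 1, 1, 0]
        groups = ["b", "a", "b", "a", "b", "a"]
        df = small_frame(times, events, groups)
        fit = fit_cox(df, reference_group="a")
        x = (np.array(groups) == "b").astype(float)
        oracle = cox_grid_oracle(times, events, x)
        assert fit.beta[0] == pytest.approx(oracle, abs=1e-4)

    def test_more_grid_oracle_fixtures(self):
        rng = np.random.default_rng(17)
        for _ in range(4):
            n = int(rng.integers(5, 9))
            times = np.round(rng.uniform(1, 20, n), 3)  # distinct w.h.p.
            events = rng.integers(0, 2, n)
            x = rng.integers(0, 2, n)
            if events.sum() == 0 or np.ptp(x) == 0:
                continue
            df = small_frame(times, events, np.where(x == 1, "b", "a"))
            oracle = cox_grid_oracle(times, events, x)
            if abs(oracle) >= 4.999:
                continue  # (quasi-)separation: the MLE is unbounded on this fixture
            fit = fit_cox(df, reference_group="a")
            assert fit.beta[0] == pytest.approx(oracle, abs=1e-4)

    def test_no_events_rejected(self):
        df = small_frame([1.0, 2.0], [0, 0], ["a", "b"])
        with pytest.raises(DegenerateDataError):
            fit_cox(df, reference_group="a")

    def test_constant_covariate_rejected(self):
        df = two_group_weibull(40, 1.0, 0).assign(ses=5.0)
        with pytest.raises(DegenerateDataError, match="ses"):
            fit_cox(df, reference_group="g0", covariates=["ses"])

    def test_matches_lifelines_with_cluster_robust_se(self):
        lifelines = pytest.importorskip("lifelines")
        df = two_group_weibull(300, 2.0, 3, family_pairs=True, frailty=0.5)
        df["time"] += np.random.default_rng(0).uniform(0, 1e-8, len(df))  # kill ties
        fit = fit_cox(df, reference_group="g0")
        cph = lifelines.CoxPHFitter()
        ldf = df.assign(g=(df.group == "g1").astype(float))[
            ["time", "event", "g", "family_id"]
        ]
        cph.fit(ldf, duration_col="time", event_col="event",
                cluster_col="family_id", robust=True, formula="g")
        assert fit.beta[0] == pytest.approx(cph.params_.iloc[0], abs=1e-6)
        assert fit.robust_se()[0] == pytest.approx(cph.standard_errors_.iloc[0], rel=1e-5)

    def test_one_subject_per_cluster_equals_unclustered_sandwich(self):
        df = two_group_weibull(120, 1.5, 5)
        a = fit_cox(df, reference_group="g0", cluster_col="family_id")
        b = fit_cox(df, reference_group="g0", cluster_col=None)
        np.testing.assert_allclose(a.cov_robust, b.cov_robust, atol=1e-8)

    def test_breslow_equals_efron_without_ties(self):
        df = two_group_weibull(150, 2.0, 7)
        a = fit_cox(df, reference_group="g0", ties="breslow")
        b = fit_cox(df, reference_group="g0", ties="efron")
        assert a.beta[0] == pytest.approx(b.beta[0], abs=1e-8)

    def test_parameter_recovery_single_cohort(self):
        df = two_group_weibull(2000, 2.7, 11)
        fit = fit_cox(df, reference_group="g0")
        se = fit.robust_se()[0]
        assert np.log(2.7) == pytest.approx(fit.beta[0], abs=3 * se)


class TestWald:
    def _null_fit(self):
        return CoxFit(
            names=["group[a]", "group[b]"], beta=np.zeros(2),
            cov_model=np.eye(2), cov_robust=np.eye(2) * 0.04,
            loglik=0.0, n=10, n_events=5, n_clusters=10, ties="breslow",
            group_labels=["r", "a", "b"], reference_group="r",
            group_terms=["group[a]", "group[b]"],
            baseline_times=np.array([1.0]), baseline_increments=np.array([0.1]),
        )

    def test_zero_coefficients_give_zero_chi2(self):
        chi2, df, p = wald_group_test(self._null_fit())
        assert chi2 == 0.0 and df == 2 and p == 1.0

    def test_one_df_equals_squared_z(self):
        data = two_group_weibull(200, 2.0, 1)
        fit = fit_cox(data, reference_group="g0")
        chi2, df, _ = wald_group_test(fit)
        z = fit.beta[0] / fit.robust_se()[0]
        assert chi2 == pytest.approx(z**2, abs=1e-10)
        assert df == 1

    def test_two_df_matches_direct_matrix_arithmetic(self):
        fit = self._null_fit()
        fit.beta = np.array([0.5, -0.2])
        V = np.array([[0.04, 0.01], [0.01, 0.09]])
        fit.cov_robust = V
        chi2, df, _ = wald_group_test(fit)
        expected = fit.beta @ np.linalg.inv(V) @ fit.beta
        assert chi2 == pytest.approx(expected, abs=1e-12)


class TestPairwise:
    def _three_group_frame(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        grp = rng.integers(0, 3, n)
        mult = np.exp([0.0, 0.6, 1.0])[grp]
        t = 18 * (rng.exponential(1, n) / mult) ** (1 / 6)
        fu = np.maximum(rng.normal(16, 2.3, n), 12)
        return small_frame(
            np.minimum(t, fu), (t < fu).astype(int),
            np.array(["a", "b", "c"])[grp],
        )

    def test_reference_flip_reciprocity(self):
        fit = fit_cox(self._three_group_frame(), reference_group="a")
        tbl = pairwise_hazard_ratios(fit).set_index(["group", "versus"])
        for a in "abc":
            for b in "abc":
                if a != b:
                    assert tbl.loc[(a, b), "hr"] == pytest.approx(
                        1.0 / tbl.loc[(b, a), "hr"], abs=1e-12
                    )

    def test_contrasts_match_rotated_reference_refits(self):
        df = self._three_group_frame(seed=5)
        fit_a = fit_cox(df, reference_group="a")
        tbl_a = pairwise_hazard_ratios(fit_a).set_index(["group", "versus"])
        for ref in ("b", "c"):
            fit_r = fit_cox(df, reference_group=ref)
            tbl_r = pairwise_hazard_ratios(fit_r).set_index(["group", "versus"])
            for pair in tbl_a.index:
                assert tbl_a.loc[pair, "hr"] == pytest.approx(
                    tbl_r.loc[pair, "hr"], abs=1e-8
                )

    def test_unknown_group_rejected(self):
        fit = fit_cox(self._three_group_frame(), reference_group="a")
        with pytest.raises(DataError):
            pairwise_hazard_ratios(fit, groups=["a", "zzz"])

    def test_holm_adjustment_is_monotone_and_bounded(self):
        fit = fit_cox(self._three_group_frame(), reference_group="a")
        tbl = pairwise_hazard_ratios(fit, holm=True)
        assert (tbl["p_holm"] >= tbl["p"] - 1e-15).all()
        assert (tbl["p_holm"] <= 1.0).all()


class TestCumulativeIncidence:
    def test_single_event_null_model_jump(self):
        n = 10
        df = small_frame(np.arange(1.0, n + 1), [0] * 4 + [1] + [0] * 5, ["g"] * n)
        fit = fit_cox(df, reference_group="g")
        ci = cumulative_incidence(fit, "g")
        # event at t=5 with 6 subjects still at risk
        assert ci["cumulative_incidence"].iloc[-1] == pytest.approx(1 - np.exp(-1 / 6))

    def test_curves_monotone_and_bounded(self):
        df = two_group_weibull(400, 2.7, 2)
        fit = fit_cox(df, reference_group="g0")
        for g in ("g0", "g1"):
            c = cumulative_incidence(fit, g)["cumulative_incidence"].to_numpy()
            assert np.all(np.diff(c) >= 0)
            assert c[0] == 0.0 and c[-1] <= 1.0

    def test_group_scaling_is_proportional(self):
        df = two_group_weibull(400, 2.7, 4)
        fit = fit_cox(df, reference_group="g0")
        c0 = cumulative_incidence(fit, "g0")["cumulative_incidence"].to_numpy()[1:]
        c1 = cumulative_incidence(fit, "g1")["cumulative_incidence"].to_numpy()[1:]
        np.testing.assert_allclose(
            np.log(1 - c1), np.log(1 - c0) * np.exp(fit.beta[0]), rtol=1e-10
        )


class TestMatchGroups:
    def _subjects(self, shifts, n=20):
        subs, groups = [], {}
        for g, shift in shifts.items():
            rng = np.random.default_rng(sum(ord(c) for c in g))
            for i in range(n):
                sid = f"{g}{i}"
                subs.append(
                    make_subject(
                        sid,
                        followup_age_years=16.0,
                        baseline_age=11.0 + shift + rng.normal(0, 1.5),
                        hyperactive_symptoms=int(np.clip(round(rng.normal(7.5, 1.2)), 0, 9)),
                    )
                )
                groups[sid] = g
        return subs, groups

    def test_equal_sized_groups_identity_selection(self):
        subs, groups = self._subjects({"a": 0.0, "b": 0.0}, n=8)
        res = match_groups(subs, groups)
        assert sorted(res.selected_ids) == sorted(groups)

    def test_target_exceeding_smallest_group_rejected(self):
        subs, groups = self._subjects({"a": 0.0, "b": 0.0}, n=8)
        with pytest.raises(DataError):
            match_groups(subs, groups, target_n=9)

    def test_matching_reduces_age_imbalance(self):
        subs, groups = self._subjects({"a": 0.0, "b": 2.0, "c": 0.5}, n=40)
        res = match_groups(subs, groups, target_n=15)
        bal = res.balance.set_index("variable")
        assert (
            bal.loc["baseline_age", "post_max_smd"]
            < bal.loc["baseline_age", "pre_max_smd"]
        )


def test_non_stimulant_users_flags_only_non_stimulant_classes():
    from conftest import dispense
    from stimtraj.io import DrugClass

    recs = [
        dispense("s1", day=10),
        dispense("s2", day=10, dose=1.0, strength=1.0,
                 drug=DrugClass.NON_STIMULANT_ANTIPSYCHOTIC),
    ]
    assert non_stimulant_users(recs) == {"s2"}
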
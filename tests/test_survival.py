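import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lnmts import cox_fit, km_estimate, logrank_test
from lnmts.survival import as_survival_arrays


class TestKaplanMeier:
    def test_closed_form_three_events(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_survival_is_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert km.times.size == 0
        assert km.survival_at(100.0) == 1.0

    def test_censored_at_event_time_stays_at_risk(self):
        # one event and one censor at t=1: n=2 at risk -> S(1)=0.5
        km = km_estimate([1.0, 1.0], [1, 0])
        assert km.survival_at(1.0) == pytest.approx(0.5)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            km_estimate([], [])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        times=st.lists(
            st.floats(0.1, 100.0, allow_nan=False), min_size=1, max_size=30
        )
    )
    def test_no_censoring_equals_empirical_survival(self, times):
        times = np.asarray(times)
        km = km_estimate(times, np.ones_like(times, dtype=int))
        grid = np.unique(times)
        empirical = (times[:, None] > grid[None, :]).mean(axis=0)
        np.testing.assert_allclose(km.survival_at(grid), empirical, atol=1e-12)

    def test_matches_analytic_exponential_limit(self):
        lam = 1 / 500.0
        rng = np.random.default_rng(123)
        n = 200
        times = rng.exponential(1 / lam, n)
        km = km_estimate(times, np.ones(n, dtype=int))
        t = np.log(2) / lam
        s_true = 0.5
        mc_se = np.sqrt(s_true * (1 - s_true) / n)
        assert abs(km.survival_at(t) - s_true) < 3 * mc_se

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(5)
        times = rng.exponential(100, 80)
        events = rng.integers(0, 2, 80)
        events[0] = 1
        km = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        grid = kmf.survival_function_.index.values[1:]
        np.testing.assert_allclose(
            km.survival_at(grid), kmf.survival_function_.values[1:, 0], atol=1e-12
        )


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 0, 1, 1, 0]
        res = logrank_test(t + t, e + e, [0] * 5 + [1] * 5)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_single_event_time_matches_hand_hypergeometric(self):
        # groups A={1 event, 2 censored-later}, B={2 censored-later}
        # at t=1: n=4, d=1, nA=2 -> E_A=0.5, V=1*(3/3)*(2/4)*(1-2/4)=0.25
        # chi2 = (1-0.5)^2 / 0.25 = 1.0
        times = [1.0, 5.0, 5.0, 5.0]
        events = [1, 0, 0, 0]
        group = ["A", "A", "B", "B"]
        res = logrank_test(times, events, group)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)
        assert res.df == 1

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(10, 60)
        events = rng.integers(0, 2, 60)
        events[:5] = 1
        group = rng.integers(0, 3, 60)
        a = logrank_test(times, events, group)
        relabeled = np.array(["xyz"[g] for g in group])
        b = logrank_test(times, events, relabeled)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_time_shift_invariance(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10, 50)
        events = rng.integers(0, 2, 50)
        events[:5] = 1
        group = rng.integers(0, 2, 50)
        a = logrank_test(times, events, group)
        b = logrank_test(times + 17.5, events, group)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_three_group_df(self):
        rng = np.random.default_rng(4)
        res = logrank_test(
            rng.exponential(10, 90), np.ones(90, int), np.repeat([0, 1, 2], 30)
        )
        assert res.df == 2

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test([1, 2], [1, 1], [0, 0])

    def test_matches_lifelines_two_group(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(6)
        times = rng.exponential(50, 100)
        events = rng.integers(0, 2, 100)
        events[:10] = 1
        group = rng.integers(0, 2, 100)
        ours = logrank_test(times, events, group)
        ref = ll_logrank(
            times[group == 0], times[group == 1], events[group == 0], events[group == 1]
        )
        assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-9)


class TestCox:
    @staticmethod
    def _binary_cohort(n, hr, seed, censor_at=None):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n).astype(float)
        lam = 0.002 * hr**x
        t = rng.exponential(1 / lam)
        e = np.ones(n, dtype=int)
        if censor_at is not None:
            e = (t <= censor_at).astype(int)
            t = np.minimum(t, censor_at)
        return t, e, x

    def test_recovers_planted_hazard_ratio(self):
        t, e, x = self._binary_cohort(1000, 2.0, seed=42)
        fit = cox_fit(t, e, x)
        assert fit.coef[0] == pytest.approx(np.log(2.0), abs=0.1)
        assert fit.converged
        assert fit.ci_lower[0] < fit.hazard_ratio[0] < fit.ci_upper[0]

    def test_consistency_at_large_n(self):
        t, e, x = self._binary_cohort(5000, 2.0, seed=7, censor_at=800.0)
        fit = cox_fit(t, e, x)
        assert fit.coef[0] == pytest.approx(np.log(2.0), abs=0.05)

    def test_constant_covariate_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1, 2, 3, 4], [1, 1, 1, 0], np.zeros(4))

    def test_more_covariates_than_subjects_is_error(self):
        with pytest.raises(ValueError, match="n > p"):
            cox_fit([1, 2], [1, 1], np.eye(2))

    def test_matches_reference_implementation_to_1e6(self):
        """Breslow and Efron fits agree with scikit-survival on 50 rows."""
        from sksurv.linear_model import CoxPHSurvivalAnalysis

        rng = np.random.default_rng(42)
        n = 50
        X = np.column_stack(
            [rng.integers(0, 2, n).astype(float), rng.normal(0, 1, n)]
        )
        t = rng.exponential(1 / (0.01 * np.exp(0.5 * X[:, 0] - 0.3 * X[:, 1])))
        e = (rng.uniform(size=n) < 0.8).astype(int)
        e[0] = 1
        y = np.array(
            [(bool(ev), tv) for ev, tv in zip(e, t)],
            dtype=[("event", bool), ("time", float)],
        )
        for ties, tt in (("breslow", t), ("efron", np.round(t / 50))):
            yy = np.array(
                [(bool(ev), tv) for ev, tv in zip(e, tt)],
                dtype=[("event", bool), ("time", float)],
            )
            ours = cox_fit(tt, e, X, ties=ties)
            ref = CoxPHSurvivalAnalysis(ties=ties, tol=1e-12).fit(X, yy)
            np.testing.assert_allclose(ours.coef, ref.coef_, atol=1e-6)

    def test_separation_is_flagged(self):
        # covariate perfectly orders the hazard -> monotone likelihood
        t = np.arange(1.0, 21.0)
        e = np.ones(20, int)
        x = (t > 10).astype(float)  # all early events in one arm
        fit = cox_fit(t, e, x)
        assert any("monotone" in w for w in fit.warnings)

    def test_tied_events_breslow_vs_efron_differ(self):
        rng = np.random.default_rng(9)
        t = np.round(rng.exponential(10, 100))
        t[t == 0] = 1
        e = rng.integers(0, 2, 100)
        e[:10] = 1
        x = rng.normal(0, 1, 100)
        b = cox_fit(t, e, x, ties="breslow")
        f = cox_fit(t, e, x, ties="efron")
        assert b.coef[0] != pytest.approx(f.coef[0], abs=1e-12)


class TestSurvivalTargetParsing:
    def test_accepts_tuple_structured_and_2col(self):
        times = np.array([1.0, 2.0, 3.0])
        events = np.array([1, 0, 1])
        structured = np.array(
            [(bool(e), t) for e, t in zip(events, times)],
            dtype=[("event", bool), ("time", float)],
        )
        for y in ((times, events), structured, np.column_stack([times, events])):
            t, e = as_survival_arrays(y)
            np.testing.assert_array_equal(t, times)
            np.testing.assert_array_equal(e, events)
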
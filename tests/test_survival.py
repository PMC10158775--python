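"""Kaplan–Meier, log-rank and Cox against hand computations, permutation
nulls, simulations with known truth, and lifelines as an independent
reference implementation."""

from fractions import Fraction

import numpy as np
import pytest

from ctmrd.survival import (
    cox_fit,
    cox_score_test,
    km_estimate,
    logrank_test,
)

# 12-subject fixture: (time, event). Hand-computed product-limit table below.
TWELVE = [
    (1, True), (2, False), (2, True), (3, True), (4, True), (4, False),
    (5, True), (6, False), (7, True), (8, True), (9, False), (10, True),
]
# S(t) after each distinct event time, as exact products of (1 - d/n):
# t=1: 11/12; t=2: *10/11; t=3: *8/9; t=4: *7/8; t=5: *5/6; t=7: *3/4;
# t=8: *2/3; t=10: *0/1
TWELVE_TABLE = {
    1: Fraction(11, 12),
    2: Fraction(5, 6),
    3: Fraction(20, 27),
    4: Fraction(35, 54),
    5: Fraction(175, 324),
    7: Fraction(175, 432),
    8: Fraction(175, 648),
    10: Fraction(0),
}


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        km = km_estimate([3, 5, 8, 9], [False] * 4)
        assert km.evaluate(100) == 1.0
        assert km.times.size == 0

    def test_single_event_among_four(self):
        km = km_estimate([5, 6, 7, 8], [True, False, False, False])
        assert km.evaluate(5) == pytest.approx(0.75)

    def test_twelve_point_hand_computed_table(self):
        times, events = zip(*TWELVE)
        km = km_estimate(times, events)
        assert list(km.times) == sorted(TWELVE_TABLE)
        for t, s in TWELVE_TABLE.items():
            assert km.evaluate(t) == pytest.approx(float(s), abs=1e-12)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        times = rng.integers(1, 20, size=50).astype(float)
        km = km_estimate(times, np.ones(50, dtype=bool))
        for t in np.unique(times):
            assert km.evaluate(t) == pytest.approx(np.mean(times > t))

    def test_curve_non_increasing_right_continuous(self):
        times, events = zip(*TWELVE)
        km = km_estimate(times, events)
        assert np.all(np.diff(km.survival) <= 1e-15)
        assert km.evaluate(0) == 1.0

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        times, events = zip(*TWELVE)
        km = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t in km.times:
            assert km.evaluate(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0])
            )

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


def two_group_fixture(seed=5, n=40, hr=2.5):
    rng = np.random.default_rng(seed)
    group = np.repeat([0, 1], n // 2)
    lam = 0.05 * hr**group
    t = rng.exponential(1 / lam)
    c = rng.uniform(5, 40, size=n)
    times = np.minimum(t, c)
    events = t <= c
    return times, events, group


class TestLogRank:
    def test_identical_groups_chi2_zero(self):
        g = ([1, 2, 3, 4], [True, True, False, True])
        chi2, p = logrank_test([g, g])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            logrank_test([([1, 2], [True, True])])

    def test_relabeling_invariance(self):
        times, events, group = two_group_fixture()
        a = [(times[group == g], events[group == g]) for g in (0, 1)]
        b = [(times[group == g], events[group == g]) for g in (1, 0)]
        assert logrank_test(a)[0] == pytest.approx(logrank_test(b)[0], rel=1e-12)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        times, events, group = two_group_fixture()
        chi2, p = logrank_test(
            [(times[group == g], events[group == g]) for g in (0, 1)]
        )
        ref = ll_logrank(
            times[group == 0], times[group == 1],
            event_observed_A=events[group == 0], event_observed_B=events[group == 1],
        )
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_single_event_time_equals_2x2_chi_square(self):
        """With all events at one time the log-rank reduces to the Pearson
        chi-square of the 2x2 (with the hypergeometric variance)."""
        # group 0: 3 events at t=5 of 6 at risk; group 1: 1 event of 6
        times0 = [5, 5, 5, 9, 9, 9]
        ev0 = [True, True, True, False, False, False]
        times1 = [5, 9, 9, 9, 9, 9]
        ev1 = [True, False, False, False, False, False]
        chi2, _ = logrank_test([(times0, ev0), (times1, ev1)])
        # hand: n=12, d=4, n0=6 -> E0=2, V = d(n-d)/(n-1) * n0 n1 / n^2 = 4*8/11 * 1/4
        v = 4 * 8 / 11 * (6 * 6) / 144
        assert chi2 == pytest.approx((3 - 2) ** 2 / v)

    def test_chi2_consistent_with_permutation_null(self):
        """Asymptotic p agrees with a 10,000-permutation Monte-Carlo p."""
        times, events, group = two_group_fixture(seed=9, n=30, hr=2.0)
        obs, p_asym = logrank_test(
            [(times[group == g], events[group == g]) for g in (0, 1)]
        )
        rng = np.random.default_rng(0)
        n_perm = 10_000
        exceed = 0
        for _ in range(n_perm):
            g = rng.permutation(group)
            chi2, _ = logrank_test([(times[g == 0], events[g == 0]), (times[g == 1], events[g == 1])])
            exceed += chi2 >= obs - 1e-12
        p_perm = exceed / n_perm
        se = np.sqrt(max(p_perm * (1 - p_perm), 1e-4) / n_perm)
        assert p_asym == pytest.approx(p_perm, abs=max(0.02, 4 * se))

    def test_null_rejection_rate_near_alpha(self):
        """Type-I error under label shuffling is ~5% at alpha = 0.05."""
        rng = np.random.default_rng(12)
        n, reps = 60, 400
        rejections = 0
        for _ in range(reps):
            times = rng.exponential(10, size=n)
            events = rng.random(n) < 0.7
            group = rng.permutation(np.repeat([0, 1], n // 2))
            _, p = logrank_test(
                [(times[group == g], events[group == g]) for g in (0, 1)]
            )
            rejections += p < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps) + 0.01


class TestCox:
    def test_recovers_hr_3_within_20pct(self):
        rng = np.random.default_rng(17)
        n = 400
        x = rng.integers(0, 2, size=n).astype(float)
        lam = 0.04 * 3.0**x
        t = rng.exponential(1 / lam)
        c = rng.uniform(10, 60, size=n)
        times, events = np.minimum(t, c), t <= c
        fit = cox_fit(x[:, None], times, events, names=["arm"])
        assert fit["arm"].hazard_ratio == pytest.approx(3.0, rel=0.2)
        assert fit["arm"].ci95_lo < 3.0 < fit["arm"].ci95_hi

    def test_null_hr_interval_coverage(self):
        """With no true effect (HR = 1, n = 500), the estimate stays within
        [0.8, 1.25] in ~95% of replicates."""
        rng = np.random.default_rng(23)
        inside = 0
        reps = 40
        for _ in range(reps):
            x = rng.integers(0, 2, size=500).astype(float)
            t = rng.exponential(20, size=500)
            c = rng.uniform(5, 50, size=500)
            times, events = np.minimum(t, c), t <= c
            fit = cox_fit(x[:, None], times, events)
            inside += 0.8 <= fit.covariates[0].hazard_ratio <= 1.25
        assert inside / reps >= 0.85  # 95% nominal minus Monte-Carlo slack

    def test_matches_lifelines_efron(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        times, events, group = two_group_fixture(seed=2, n=80, hr=2.0)
        rng = np.random.default_rng(8)
        x2 = rng.normal(size=80)
        X = np.column_stack([group.astype(float), x2])
        fit = cox_fit(X, times, events, names=["grp", "cont"])
        df = pd.DataFrame({"T": times, "E": events, "grp": X[:, 0], "cont": X[:, 1]})
        ref = CoxPHFitter().fit(df, duration_col="T", event_col="E")
        for name in ("grp", "cont"):
            assert fit[name].coef == pytest.approx(ref.params_[name], abs=1e-6)
            assert fit[name].se == pytest.approx(ref.standard_errors_[name], abs=1e-6)

    def test_score_test_equals_logrank_without_ties(self):
        rng = np.random.default_rng(31)
        n = 60
        group = np.repeat([0, 1], n // 2).astype(float)
        times = rng.exponential(10 + 5 * group)  # continuous: no ties
        events = rng.random(n) < 0.8
        assert len(np.unique(times)) == n
        chi2, _ = logrank_test(
            [(times[group == g], events[group == g]) for g in (0, 1)]
        )
        score = cox_score_test(group[:, None], times, events)
        assert score == pytest.approx(chi2, abs=1e-6)

    def test_univariate_screening_excludes_null_covariate(self):
        rng = np.random.default_rng(41)
        n = 300
        signal = rng.integers(0, 2, size=n).astype(float)
        noise = rng.normal(size=n) * 0.01  # unrelated to hazard
        t = rng.exponential(1 / (0.05 * 3.0**signal))
        c = rng.uniform(5, 50, size=n)
        times, events = np.minimum(t, c), t <= c
        fit = cox_fit(
            np.column_stack([signal, noise]), times, events,
            names=["signal", "noise"], selection="univariate_first",
        )
        assert "noise" in fit.excluded
        assert [c.name for c in fit.covariates] == ["signal"]
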
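"""Group-comparison tests: closed-form checks against scipy and
independent oracles, published-value reproduction, BH correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import cortclust as cc
from cortclust.stats import apply_alpha_policy, bh_adjust, run_battery
from tests.conftest import exact_moment_sample


class TestWelchT:
    def test_identical_summaries_give_t0_p1(self):
        r = cc.welch_t((5.0, 2.0, 10), (5.0, 2.0, 10))
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_published_age_comparison(self):
        # remission vs non-remission age; the table prints 0.5998, which
        # only reproduces under the population-SD reading of its summaries
        r = cc.welch_t((45.1, 15.2, 77), (43.1, 13.3, 17))
        assert r.p_value == pytest.approx(0.5895, abs=5e-4)
        r0 = cc.welch_t((45.1, 15.2, 77), (43.1, 13.3, 17), sd_ddof=0)
        assert r0.p_value == pytest.approx(0.5998, abs=2e-3)

    def test_matches_scipy_on_raw_data(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=30), rng.normal(loc=0.5, size=20)
        r = cc.welch_t_raw(a, b)
        t, p = sps.ttest_ind(a, b, equal_var=False)
        assert r.statistic == pytest.approx(t, abs=1e-12)
        assert r.p_value == pytest.approx(p, abs=1e-12)
        rp = cc.welch_t_raw(a, b, equal_var=True)
        t2, p2 = sps.ttest_ind(a, b, equal_var=True)
        assert rp.p_value == pytest.approx(p2, abs=1e-12)

    def test_larger_n_sharpens_a_fixed_difference(self):
        ps = [cc.welch_t((10, 3, n), (11, 3, n)).p_value
              for n in (5, 10, 20, 40, 80)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_zero_variance_degenerate(self):
        r = cc.welch_t((5.0, 0.0, 5), (5.0, 0.0, 5))
        assert r.degenerate and r.p_value == 1.0


class TestOnewayAnova:
    def test_equal_groups_give_f0_p1(self):
        r = cc.oneway_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_raw_and_summary_entry_points_agree(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(loc=m, size=n)
                  for m, n in [(0, 8), (1, 12), (0.5, 7)]]
        r_raw = cc.oneway_anova(groups)
        r_sum = cc.oneway_anova_from_summary(
            [g.mean() for g in groups], [g.std(ddof=1) for g in groups],
            [len(g) for g in groups])
        assert r_raw.statistic == pytest.approx(r_sum.statistic, rel=1e-12)
        f, p = sps.f_oneway(*groups)
        assert r_raw.statistic == pytest.approx(f, rel=1e-12)
        assert r_raw.p_value == pytest.approx(p, rel=1e-9)

    def test_published_age_across_clusters(self):
        r = cc.oneway_anova_from_summary([46.7, 54.2, 40.6],
                                         [15.3, 10.8, 14.8], [23, 15, 39])
        assert r.p_value == pytest.approx(0.00826, abs=5e-5)
        r0 = cc.oneway_anova_from_summary([46.7, 54.2, 40.6],
                                          [15.3, 10.8, 14.8], [23, 15, 39],
                                          sd_ddof=0)
        assert r0.p_value == pytest.approx(0.0094, abs=5e-4)

    def test_all_identical_values_degenerate(self):
        r = cc.oneway_anova([[2.0, 2.0, 2.0], [2.0, 2.0]])
        assert r.degenerate and r.p_value == 1.0


class TestChiSquare:
    def test_published_male_proportion(self):
        r = cc.chi_square_2xk([[32, 45], [8, 9]])
        assert round(r.p_value, 4) == 0.8854
        assert r.note == "yates"

    def test_proportional_table_gives_chi2_zero(self):
        r = cc.chi_square_2xk([[10, 20], [20, 40]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_yates_never_below_uncorrected_p(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            t = rng.integers(1, 40, size=(2, 2))
            p_yates = cc.chi_square_2xk(t).p_value
            p_plain = sps.chi2_contingency(t, correction=False)[1]
            assert p_yates >= p_plain - 1e-12

    def test_agrees_with_permutation_oracle_on_3x2_table(self):
        table = np.array([[20, 20], [15, 25], [30, 10]])
        r = cc.chi_square_2xk(table)
        labels = np.repeat([0, 1, 2], table.sum(axis=1))
        x = np.repeat([1, 0], table.sum(axis=0))
        rng = np.random.default_rng(0)
        n_hits, n_perm = 0, 20_000
        for _ in range(n_perm):
            rng.shuffle(x)
            tt = np.array([[x[labels == g].sum(), (x[labels == g] == 0).sum()]
                           for g in range(3)])
            s = sps.chi2_contingency(tt, correction=False)[0]
            n_hits += s >= r.statistic - 1e-12
        assert abs(r.p_value - n_hits / n_perm) < 0.02

    def test_zero_margin_flagged_undefined(self):
        r = cc.chi_square_2xk([[0, 5], [0, 7]])
        assert r.degenerate and np.isnan(r.p_value)

    def test_group_relabeling_invariance(self):
        t = np.array([[12, 8], [5, 15], [9, 9]])
        assert cc.chi_square_2xk(t).p_value == pytest.approx(
            cc.chi_square_2xk(t[::-1]).p_value)


class TestBHAdjust:
    def test_published_battery_arithmetic(self):
        # 20 of 58 tests passing the step-up yields the printed 0.0172
        p = np.concatenate([np.linspace(1e-5, 20 / 58 * 0.05, 20),
                            np.linspace(0.6, 0.99, 38)])
        res = bh_adjust(p, q=0.05)
        assert res.n_rejected == 20
        assert res.adjusted_alpha == pytest.approx(0.0172, abs=5e-5)

    def test_all_ones_reject_nothing(self):
        res = bh_adjust(np.ones(10), q=0.05)
        assert not res.significant.any()
        assert res.adjusted_alpha == pytest.approx(0.005)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bh_adjust([])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40),
           st.floats(0.01, 0.2))
    def test_step_up_matches_brute_force_oracle(self, p, q):
        p = np.asarray(p)
        res = bh_adjust(p, q=q)
        # oracle: try every candidate rank explicitly
        m = len(p)
        ps = np.sort(p)
        best = 0
        for i in range(1, m + 1):
            if ps[i - 1] <= i / m * q:
                best = i
        assert res.n_rejected == best
        assert res.significant.sum() == best

    def test_matches_statsmodels_rejections(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.random(58) ** 2
            res = bh_adjust(p, q=0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            np.testing.assert_array_equal(res.significant, ref)

    def test_relabeling_order_invariance(self):
        p = np.array([0.001, 0.2, 0.04, 0.8, 0.011])
        a = bh_adjust(p, 0.05)
        perm = np.array([3, 0, 4, 1, 2])
        b = bh_adjust(p[perm], 0.05)
        np.testing.assert_array_equal(a.significant[perm], b.significant)


class TestAlphaPolicies:
    def test_bonferroni_and_fixed(self):
        p = np.array([0.001, 0.02, 0.3])
        flags, alpha = apply_alpha_policy(p, policy="bonferroni", q=0.05)
        assert alpha == pytest.approx(0.05 / 3)
        np.testing.assert_array_equal(flags, [True, False, False])
        flags, alpha = apply_alpha_policy(p, policy="fixed:0.025", q=0.05)
        np.testing.assert_array_equal(flags, [True, True, False])

    def test_nan_p_values_never_flagged(self):
        flags, _ = apply_alpha_policy([0.001, np.nan], policy="bh")
        assert flags[0] and not flags[1]


class TestRunBattery:
    def test_battery_over_synthetic_cohort(self, remission_cohort, fitted_kpod):
        cov = cc.add_trajectory_features(remission_cohort.covariates,
                                         remission_cohort.trajectories)
        battery = run_battery(cov, fitted_kpod.labels_)
        assert battery.m == len(battery.results)
        assert battery.m == 17  # 9 continuous + 8 categorical
        assert 0 < battery.adjusted_alpha <= battery.q
        frame = cc.battery_to_frame(battery)
        assert len(frame) == battery.m
        # trajectory-derived features must separate the trajectory clusters
        by_var = {r.variable: r for r in battery.results}
        assert by_var["initial_cortisol"].p_value < 1e-4

    def test_two_group_battery_uses_welch(self, remission_cohort):
        cov = remission_cohort.covariates
        labels = (np.arange(len(cov)) % 2).astype(int)
        battery = run_battery(cov, labels, continuous=("age",),
                              categorical=("male",))
        kinds = {r.variable: r.test_kind for r in battery.results}
        assert kinds == {"age": "t_test", "male": "chi_square"}
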
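"""Whole-tree trend/drift search: rescaling, rank test, null families, verdicts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import trendtree as tt
from trendtree.ridge import RidgeEngine
from trendtree.trend import pipeline_statistics, rank_p, rescale01, simulate_null_batch


class TestRescale01:
    def test_simple_example(self):
        np.testing.assert_allclose(rescale01(np.array([2.0, 4.0, 6.0])), [0, 0.5, 1])

    def test_unit_interval_fixed(self):
        v = np.array([0.0, 0.25, 1.0])
        np.testing.assert_allclose(rescale01(v), v)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            rescale01(np.ones(5))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=30).filter(
            lambda v: max(v) - min(v) > 1e-6
        ),
        st.floats(0.01, 100),
        st.floats(-1e3, 1e3),
    )
    def test_affine_invariance(self, v, a, b):
        v = np.asarray(v)
        np.testing.assert_allclose(rescale01(a * v + b), rescale01(v), atol=1e-9)


class TestRankP:
    def test_above_all_nulls(self):
        assert rank_p(1000.0, np.arange(100.0)) == pytest.approx(101 / 101)

    def test_below_all_nulls(self):
        assert rank_p(-1.0, np.arange(100.0)) == pytest.approx(1 / 101)

    def test_never_exactly_zero(self, rng):
        null = rng.normal(size=100)
        for obs in rng.normal(size=50):
            assert rank_p(obs, null) >= 1 / 101

    def test_uniform_under_exchangeability(self, rng):
        # observed drawn from the null itself: per-tail rejection near 5%
        hits_hi = hits_lo = trials = 0
        for _ in range(40):
            null = rng.normal(size=100)
            obs = rng.normal(size=50)
            for o in obs:
                p = rank_p(o, null)
                hits_hi += p > 0.95
                hits_lo += p < 0.05
                trials += 1
        assert 0.02 <= hits_hi / trials <= 0.10
        assert 0.02 <= hits_lo / trials <= 0.10


class TestNullFamilies:
    def test_fixed_seed_identical(self, small_bd_tree):
        y = tt.simulate_bm(small_bd_tree, 1.0, seed=0)
        m = tt.TrendSearch(small_bd_tree, y, n_null=50)
        a = m.bm_null_slopes(seed=5)
        b = m.bm_null_slopes(seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_null_trend_slopes_positive_on_average(self, bd_tree):
        # Brownian rate magnitudes grow toward the present, so the null
        # family is not centered at zero - the test is rank-based, not
        # zero-based
        y = tt.simulate_bm(bd_tree, 1.0, seed=1)
        null = tt.TrendSearch(bd_tree, y, n_null=100).bm_null_slopes(seed=2)
        assert null["trend"].mean() > 0

    def test_rank_se_halves_with_four_times_nulls(self, small_bd_tree):
        # binomial scaling of the rank probability's resolution
        y = tt.simulate_bm(small_bd_tree, 1.0, seed=3)
        m = tt.TrendSearch(small_bd_tree, y)
        se = {}
        for n in (50, 200):
            reps = []
            for s in range(20):
                m.n_null = n
                reps.append(m.fit(seed=s).trend_p)
            se[n] = np.std(reps)
        assert se[200] < se[50]

    def test_bm_true_mode_shapes(self, small_bd_tree):
        rng = np.random.default_rng(0)
        rates, nodes, tips = simulate_null_batch(small_bd_tree, 7, rng, null_mode="bm_true")
        assert rates.shape == (small_bd_tree.n_branches, 7)
        assert nodes.shape == (small_bd_tree.n_nodes, 7)
        assert tips.shape == (small_bd_tree.n_tips, 7)


class TestPipelineStatistics:
    def test_monotone_rate_construction_gives_positive_slope(self, bd_tree):
        rates = np.exp(bd_tree.age[1:])
        nodes = np.linspace(0, 1, bd_tree.n_nodes)
        tips = np.linspace(0, 1, bd_tree.n_tips)
        trend, _, _ = pipeline_statistics(bd_tree, rates, nodes, tips)
        assert trend[0] > 0

    def test_age_shuffled_rates_center_on_zero(self, bd_tree, rng):
        rates = np.exp(rng.normal(size=bd_tree.n_branches))
        slopes = []
        for _ in range(300):
            perm = rng.permutation(bd_tree.n_branches)
            trend, _, _ = pipeline_statistics(
                bd_tree, rates[perm], np.ones(bd_tree.n_nodes), np.linspace(0, 1, bd_tree.n_tips)
            )
            slopes.append(trend[0])
        mean_se = np.std(slopes) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes)) < 4 * mean_se

    def test_linear_phenotype_gives_extreme_drift_rank(self, bd_tree):
        # phenotype exactly linear in age: drift slope at the top of any
        # Brownian null family
        y = pd.Series(2.0 + 0.5 * bd_tree.age[bd_tree.tip_indices],
                      index=bd_tree.tip_labels)
        res = tt.TrendSearch(bd_tree, y, n_null=100).fit(seed=0)
        assert res.drift_slope > 0
        assert res.drift_p > 0.95
        assert res.drift_verdict == "+"

    def test_identical_rates_in_both_halves_unremarkable(self, bd_tree):
        rates = np.ones(bd_tree.n_branches) + 0.01 * np.arange(bd_tree.n_branches) % 2
        _, _, sd_ratio = pipeline_statistics(
            bd_tree, rates, np.linspace(0, 1, bd_tree.n_nodes), np.linspace(0, 1, bd_tree.n_tips)
        )
        assert sd_ratio[0] == pytest.approx(1.0, rel=0.5)


class TestNamedRegressions:
    def test_slopes_match_pipeline_statistics(self, bd_tree):
        from trendtree.trend import drift_regression, trend_regression

        y = tt.simulate_bm(bd_tree, 1.0, seed=44)
        ridge = tt.PhyloRidge(bd_tree, y).fit()
        t, d, _ = pipeline_statistics(
            bd_tree, ridge.rates.to_numpy(), ridge.node_estimates.to_numpy(), y.to_numpy()
        )
        tr = trend_regression(ridge)
        dr = drift_regression(ridge)
        assert tr.params[1] == pytest.approx(t[0], rel=1e-9)
        assert dr.params[1] == pytest.approx(d[0], rel=1e-9)
        assert 0 <= tr.rsquared <= 1  # diagnostics available


class TestSearchResults:
    def test_bitwise_reproducibility(self, bd_tree):
        y = tt.simulate_bm(bd_tree, 2.0, seed=8)
        a = tt.search_trend(bd_tree, y, n_null=60, seed=17)
        b = tt.search_trend(bd_tree, y, n_null=60, seed=17)
        assert a.to_dict() == b.to_dict()
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_report_fields(self, bd_tree):
        y = tt.simulate_bm(bd_tree, 2.0, seed=8)
        res = tt.search_trend(bd_tree, y, n_null=60, seed=17)
        d = res.to_dict()
        assert 0 < d["trend_p"] < 1 and 0 < d["drift_p"] < 1
        assert d["n_null"] == 60
        assert d["trend_verdict"] in "+-none" and d["drift_verdict"] in "+-none"
        assert len(res.table) == bd_tree.n_elements
        assert "summary" not in d  # summary is a method, not a field
        assert "rate trend" in res.summary()

    def test_trend_detected_on_strongly_transformed_trait(self, bd_tree):
        y = tt.simulate_bm(bd_tree, 1.0, seed=21)
        y_neg = tt.apply_trend(y, bd_tree, -0.5)  # strong rate decline
        res = tt.search_trend(bd_tree, y_neg, n_null=100, seed=22)
        assert res.trend_verdict == "-"

    def test_sd_concordance_modes_run(self, small_bd_tree):
        y = tt.simulate_bm(small_bd_tree, 1.0, seed=30)
        for mode in ("direction", "significance", "none"):
            res = tt.TrendSearch(small_bd_tree, y, n_null=50, sd_concordance=mode).fit(seed=1)
            assert res.trend_verdict in ("+", "-", "none")
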
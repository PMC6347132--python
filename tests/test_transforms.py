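"""es / ds phenotype transforms and the dev / spread deviation metrics."""

import numpy as np
import pandas as pd
import pytest

import trendtree as tt
from trendtree.experiments import standard_replicate, _tips
from trendtree.transforms import (
    apply_drift_elements,
    apply_trend_elements,
    pic_sigma2,
)


@pytest.fixture(scope="module")
def bm_trait(bd_tree):
    return tt.simulate_bm(bd_tree, sigma2=2.0, root_value=1.0, seed=11)


class TestIdentities:
    def test_es_one_is_identity(self, bd_tree, bm_trait):
        out = tt.apply_trend(bm_trait, bd_tree, 1.0)
        assert (out == bm_trait).all()

    def test_ds_zero_is_identity(self, bd_tree, bm_trait):
        out = tt.apply_drift(bm_trait, bd_tree, 0.0)
        assert (out == bm_trait).all()

    def test_trend_formula_value(self):
        tree = tt.read_newick("(A:2,B:2);")
        y = pd.Series([3.0, 5.0], index=["A", "B"])
        out = tt.apply_trend(y, tree, 2.0)
        assert out["A"] == pytest.approx(3 * 4 / 2)

    def test_drift_formula_value(self):
        tree = tt.read_newick("(A:2,B:2);")
        y = pd.Series([1.0, 1.0], index=["A", "B"])
        out = tt.apply_drift(y, tree, 0.5)
        assert out["A"] == pytest.approx(2.0)


class TestCladeScope:
    def test_outside_clade_untouched(self, bd_tree, bm_trait):
        from trendtree.experiments import pick_random_clade

        clade = pick_random_clade(bd_tree, np.random.default_rng(0))
        for out in (
            tt.apply_clade_trend(bm_trait, bd_tree, clade, 1.6),
            tt.apply_clade_drift(bm_trait, bd_tree, clade, 0.25),
        ):
            outside = [t for t in bd_tree.tip_labels if t not in clade.tip_labels]
            assert (out[outside] == bm_trait[outside]).all()
            inside_changed = (out[clade.tip_labels] != bm_trait[clade.tip_labels]).any()
            assert inside_changed

    def test_whole_tree_clade_degenerates_to_global_transform(self, bd_tree, bm_trait):
        root_clade = bd_tree.clade(bd_tree.labels[0])
        a = tt.apply_clade_trend(bm_trait, bd_tree, root_clade, 0.8)
        b = tt.apply_trend(bm_trait, bd_tree, 1.6)
        pd.testing.assert_series_equal(a, b)

    def test_clade_drift_offset_inverts_algebraically(self, bd_tree, bm_trait):
        from trendtree.experiments import pick_random_clade

        clade = pick_random_clade(bd_tree, np.random.default_rng(1))
        ds_sig = 0.4
        out = tt.apply_clade_drift(bm_trait, bd_tree, clade, ds_sig)
        t = bd_tree.age[clade.tip_indices]
        added = (out[clade.tip_labels] - bm_trait[clade.tip_labels]).to_numpy()
        np.testing.assert_allclose(added / t, 2 * ds_sig * clade.h_ratio, rtol=1e-9)

    def test_h_ratio_linearity(self, bd_tree, bm_trait):
        from trendtree.experiments import pick_random_clade

        clade = pick_random_clade(bd_tree, np.random.default_rng(2))
        a = tt.apply_clade_drift(bm_trait, bd_tree, clade, 0.1)
        b = tt.apply_clade_drift(bm_trait, bd_tree, clade, 0.2)
        np.testing.assert_allclose(
            (b - bm_trait).to_numpy(), 2 * (a - bm_trait).to_numpy(), atol=1e-12
        )


class TestTrendVariancePattern:
    def test_es_above_one_inflates_recent_variance(self):
        # paired Monte Carlo: the recent/old age-tertile variance ratio grows
        # after an es > 1 transform relative to the untransformed trait
        wins = 0
        n = 60
        for rs in range(n):
            tree, vals, _ = standard_replicate(rs, min_tips=80)
            centered = vals - vals[tree.tip_indices].mean()
            v = apply_trend_elements(centered, tree, 1.8)
            ages = tree.age[tree.tip_indices]
            lo, hi = np.quantile(ages, [1 / 3, 2 / 3])

            def ratio(values):
                y = values[tree.tip_indices]
                return y[ages > hi].var() / y[ages <= lo].var()

            wins += ratio(v) > ratio(centered)
        assert wins / n >= 0.95


class TestDev:
    def test_dev_zero_in_expectation_under_bm(self):
        devs = []
        for rs in range(40):
            tree, vals, params = standard_replicate(rs + 50)
            y = _tips(tree, vals)
            devs.append(tt.dev_metric(y, y, tree, root_value=params["root_value"]))
        assert abs(np.mean(devs)) < 0.05

    def test_dev_odd_in_ds(self):
        # paired seeds: mean dev at +ds cancels mean dev at -ds
        ups, dns = [], []
        for rs in range(30):
            tree, vals, params = standard_replicate(rs + 150)
            y = _tips(tree, vals)
            sd = float(y.std(ddof=0))
            ups.append(tt.dev_metric(y, tt.apply_drift(y, tree, 0.5 * sd), tree,
                                     root_value=params["root_value"]))
            dns.append(tt.dev_metric(y, tt.apply_drift(y, tree, -0.5 * sd), tree,
                                     root_value=params["root_value"]))
        assert abs(np.mean(ups) + np.mean(dns)) < 0.3 * np.mean(np.abs(ups))

    def test_dev_grows_with_drift_intensity(self):
        from scipy.stats import spearmanr

        tree, vals, params = standard_replicate(78)
        y = _tips(tree, vals)
        sd = float(y.std(ddof=0))
        ds = np.linspace(0, 2, 50)
        devs = [
            tt.dev_metric(y, tt.apply_drift(y, tree, d * sd), tree,
                          root_value=params["root_value"])
            for d in ds
        ]
        rho = spearmanr(ds, devs).statistic
        assert rho > 0.8

    def test_dev_calibration_at_threshold_drift(self):
        # drifting at 0.25 trait-SD per unit time displaces the mean by about
        # 0.18 SD per unit time (mean tip age is ~85% of tree height)
        devs = []
        for rs in range(60):
            tree, vals, params = standard_replicate(rs + 300)
            y = _tips(tree, vals)
            sd = float(y.std(ddof=0))
            yd = tt.apply_drift(y, tree, 0.25 * sd)
            devs.append(tt.dev_metric(y, yd, tree, root_value=params["root_value"]))
        assert np.mean(np.abs(devs)) == pytest.approx(0.18, abs=0.05)


class TestSpread:
    def test_bm_self_normalizes_near_one(self):
        # the late/early range ratio is heavy-tailed replicate to replicate,
        # but its Brownian-normalized center sits at 1
        vals01 = []
        for rs in range(30):
            tree, vals, _ = standard_replicate(rs + 600)
            vals01.append(tt.spread_metric(vals, tree, seed=rs))
        assert 0.85 <= np.mean(vals01) <= 1.2
        assert np.mean([(0.5 <= s <= 2.0) for s in vals01]) >= 0.9

    def test_monotone_in_es(self):
        means = []
        for es in (0.3, 1.0, 1.6):
            acc = []
            for rs in range(25):
                tree, vals, _ = standard_replicate(rs + 700)
                acc.append(tt.spread_metric(apply_trend_elements(vals, tree, es), tree, seed=rs))
            means.append(np.mean(acc))
        assert means[0] < means[1] < means[2]

    def test_tip_only_input_uses_ridge_estimates(self, small_bd_tree):
        y = tt.simulate_bm(small_bd_tree, 1.0, seed=5)
        s = tt.spread_metric(y, small_bd_tree, n_bm_reference=50, seed=6)
        assert 0.3 < s < 3.0


class TestPIC:
    def test_sigma2_recovers_generating_rate(self):
        est = []
        for rs in range(30):
            tree = tt.simulate_bd_tree(min_tips=60, num_extant=60, seed=rs)
            y = tt.simulate_bm(tree, sigma2=3.0, root_value=-2.0, seed=rs)
            est.append(pic_sigma2(tree, y)[0])
        assert np.mean(est) == pytest.approx(3.0, rel=0.15)
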
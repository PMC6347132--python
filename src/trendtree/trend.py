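"""Whole-tree tests for temporal trends in evolutionary rate and phenotypic mean.

Two ordinary regressions are run on a fitted phylogenetic ridge result:

* trend - log of the 0-1 rescaled rate magnitudes against branch age; a
  systematic change of rate magnitude through time tilts this slope away from
  its Brownian expectation (which is itself positive, because Brownian rate
  magnitudes grow toward the present);
* drift - the 0-1 rescaled phenotype vector (ancestral estimates collated
  with tip values) against element age; a directional change of the
  phenotypic mean tilts this slope.

Neither slope is compared to zero.  Significance is the rank of the observed
slope within a family of slopes obtained by simulating Brownian traits
(sigma^2 = 1) on the same tree and pushing each through the identical
pipeline (same root-estimation rule, same penalty policy, same rescaling and
logging).  Rank probabilities use the (k+1)/(n+1) convention; P > 0.95 flags
an increasing and P < 0.05 a decreasing pattern.

A positive rate trend also leaves the standard deviation of rates in the
older half of the tree significantly smaller than in the recent half; the
half-tree SD ratio, ranked against the same Brownian families, arbitrates the
direction of rate variation before a trend is reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ridge import PhyloRidge, PhyloRidgeResults, RidgeEngine
from .simulate import simulate_bm_elements
from .tree import Phylogeny, validate_trait

__all__ = [
    "rescale01",
    "rank_p",
    "pipeline_statistics",
    "simulate_null_batch",
    "trend_regression",
    "drift_regression",
    "TrendSearch",
    "TrendSearchResults",
    "search_trend",
    "LOG_EPS",
]

#: offset added before logging rescaled rate magnitudes (the rescaled minimum
#: is exactly 0); shared by observed and null pipelines, so rank comparisons
#: are invariant to its exact value
LOG_EPS = 1e-4


def rescale01(v: np.ndarray) -> np.ndarray:
    """Affine rescale to [0, 1]; columnwise for 2-D input.

    Raises on a constant vector (the range is the scale unit).
    """
    v = np.asarray(v, dtype=float)
    lo = v.min(axis=0)
    span = v.max(axis=0) - lo
    if np.any(span <= 0):
        raise ValueError("cannot rescale a constant vector to [0, 1]")
    return (v - lo) / span


def rank_p(observed: float, null: np.ndarray) -> float:
    """Rank probability of an observed statistic within a null family.

    ``(number of null values below the observation + 1) / (n + 1)`` - never
    exactly 0 (an observation below every null scores 1/(n+1)).  Values above
    0.95 or below 0.05 are read as significant increases / decreases.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null family")
    return float((np.sum(null < observed) + 1) / (null.size + 1))


def _slopes(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """OLS slope of each column of Y on x."""
    xc = x - x.mean()
    return xc @ (Y - Y.mean(axis=0)) / (xc @ xc)


def simulate_null_batch(
    tree: Phylogeny,
    n: int,
    rng: np.random.Generator,
    null_mode: str = "pipeline",
    engine: RidgeEngine | None = None,
):
    """Simulate ``n`` Brownian null replicates and their rates and node values.

    Returns ``(rates, node_values, tip_values)`` with shapes (branches x n),
    (nodes x n), (tips x n).  Two constructions of the null are supported:

    * ``"bm_true"`` - rates are the true per-branch Brownian increments
      divided by branch length, and node values are the true simulated states
      (the Brownian process itself defines the null family);
    * ``"pipeline"`` - each null trait's tips are refit by phylogenetic ridge
      regression with the shared penalty policy, so the null family reflects
      estimated rather than true rates.
    """
    sims = simulate_bm_elements(tree, n, sigma2=1.0, rng=rng)
    tips = sims[tree.tip_indices]
    if null_mode == "bm_true":
        rates = (sims[1:] - sims[tree.parent[1:]]) / tree.edge_length[1:, None]
        node_vals = sims[tree.node_indices]
    elif null_mode == "pipeline":
        if engine is None:
            engine = RidgeEngine(tree)
        rates, node_vals, _, _, _ = engine.fit_batch(tips)
    else:
        raise ValueError("null_mode must be 'bm_true' or 'pipeline'")
    return rates, node_vals, tips


def _branch_age(tree: Phylogeny, mode: str) -> np.ndarray:
    """Age of each branch: its child element's age, or the branch midpoint."""
    if mode == "child":
        return tree.age[1:]
    if mode == "midpoint":
        return tree.age[1:] - tree.edge_length[1:] / 2.0
    raise ValueError("branch age mode must be 'child' or 'midpoint'")


def pipeline_statistics(
    tree: Phylogeny,
    rates: np.ndarray,
    node_est: np.ndarray,
    tip_values: np.ndarray,
    eps: float = LOG_EPS,
    age_mode: str = "child",
):
    """Trend slope, drift slope, and half-tree SD ratio for each column.

    ``rates`` is (branches x k), ``node_est`` (nodes x k), ``tip_values``
    (tips x k); 1-D input is treated as a single column.
    """
    rates = np.atleast_2d(rates.T).T
    node_est = np.atleast_2d(node_est.T).T
    tip_values = np.atleast_2d(tip_values.T).T
    b_age = _branch_age(tree, age_mode)
    log_rates = np.log(rescale01(np.abs(rates)) + eps)
    trend = _slopes(b_age, log_rates)
    phen = np.empty((tree.n_elements, rates.shape[1]))
    phen[tree.node_indices] = node_est
    phen[tree.tip_indices] = tip_values
    drift = _slopes(tree.age, rescale01(phen))
    mid = tree.age[1:] - tree.edge_length[1:] / 2.0
    older = mid <= tree.tree_height / 2.0
    if not older.any() or older.all():
        raise ValueError("no branches on one side of half tree height")
    sd_ratio = rates[older].std(axis=0) / rates[~older].std(axis=0)
    return trend, drift, sd_ratio


def trend_regression(ridge: PhyloRidgeResults, eps: float = LOG_EPS,
                     age_mode: str = "child"):
    """OLS of log rescaled |rate| on branch age, with diagnostics.

    Returns a fitted statsmodels results object; ``.params[1]`` is the trend
    slope ranked by :class:`TrendSearch`.
    """
    import statsmodels.api as sm

    tree = ridge.tree
    if tree.n_branches < 3:
        raise ValueError("need at least 3 branches for the trend regression")
    v = np.log(rescale01(np.abs(ridge.rates.to_numpy())) + eps)
    X = sm.add_constant(_branch_age(tree, age_mode))
    return sm.OLS(v, X).fit()


def drift_regression(ridge: PhyloRidgeResults):
    """OLS of the rescaled phenotype vector (nodes + tips) on element age."""
    import statsmodels.api as sm

    tab = ridge.predict_phenotype_vector()
    v = rescale01(tab["phenotype"].to_numpy())
    X = sm.add_constant(tab["age"].to_numpy())
    return sm.OLS(v, X).fit()


class TrendSearch:
    """Model object for the rate-trend / phenotypic-drift search on one tree.

    Parameters
    ----------
    tree : Phylogeny
    y : Series
        Tip-keyed trait.
    n_null : int
        Size of the Brownian null slope family (100 by default).
    lam : "auto" or float
        Ridge penalty policy, shared by observed and null fits.
    sd_concordance : {"direction", "significance", "none"}
        How the half-tree SD check gates a trend verdict: the SD ratio must
        fall on the matching side of the null family's median ("direction",
        default), be itself rank-significant ("significance"), or is ignored
        ("none", rank-only verdicts).
    age_mode : {"child", "midpoint"}
        Which age represents a branch in the trend regression.
    """

    def __init__(
        self,
        tree: Phylogeny,
        y: pd.Series,
        n_null: int = 100,
        lam="auto",
        sd_concordance: str = "direction",
        age_mode: str = "child",
        eps: float = LOG_EPS,
        null_mode: str = "pipeline",
    ):
        if sd_concordance not in ("direction", "significance", "none"):
            raise ValueError("sd_concordance must be direction|significance|none")
        self.tree = tree
        self.y = validate_trait(tree, y)
        self.n_null = int(n_null)
        self.lam = lam
        self.sd_concordance = sd_concordance
        self.age_mode = age_mode
        self.eps = float(eps)
        self.null_mode = null_mode

    @classmethod
    def from_files(cls, tree_path, trait_path, **kwargs) -> "TrendSearch":
        from .tree import read_newick, read_trait_csv

        with open(tree_path) as fh:
            tree = read_newick(fh.read())
        return cls(tree, read_trait_csv(trait_path), **kwargs)

    # ------------------------------------------------------------------- fit
    def fit(
        self,
        seed: int | None = None,
        engine: RidgeEngine | None = None,
        null: pd.DataFrame | None = None,
    ) -> "TrendSearchResults":
        tree = self.tree
        if engine is None:
            engine = RidgeEngine(tree, lam=self.lam)
        ridge = PhyloRidge(tree, self.y, lam=self.lam).fit(engine=engine)
        obs_trend, obs_drift, obs_sd = pipeline_statistics(
            tree,
            ridge.rates.to_numpy(),
            ridge.node_estimates.to_numpy(),
            self.y.to_numpy(),
            eps=self.eps,
            age_mode=self.age_mode,
        )
        if null is None:
            null = self.bm_null_slopes(seed=seed, engine=engine)
        return TrendSearchResults(
            self,
            ridge,
            float(obs_trend[0]),
            float(obs_drift[0]),
            float(obs_sd[0]),
            null,
            seed,
        )

    def bm_null_slopes(self, seed: int | None = None, engine: RidgeEngine | None = None) -> pd.DataFrame:
        """Family of null statistics from Brownian traits on the same tree.

        Each of ``n_null`` sigma^2 = 1 Brownian replicates yields one trend
        slope, one drift slope, and one SD ratio through the same rescaling
        and logging as the observed statistic (see
        :func:`simulate_null_batch` for the two null constructions).
        """
        tree = self.tree
        rng = np.random.default_rng(seed)
        rates, node_est, tips = simulate_null_batch(
            tree, self.n_null, rng, null_mode=self.null_mode, engine=engine
        )
        trend, drift, sd = pipeline_statistics(
            tree, rates, node_est, tips, eps=self.eps, age_mode=self.age_mode
        )
        return pd.DataFrame({"trend": trend, "drift": drift, "sd_ratio": sd})


class TrendSearchResults:
    """Slopes, rank probabilities, verdicts, and the per-element table."""

    def __init__(self, model, ridge: PhyloRidgeResults, trend_slope, drift_slope,
                 sd_ratio, null: pd.DataFrame, seed):
        self.model = model
        self.ridge = ridge
        self.tree = model.tree
        self.trend_slope = trend_slope
        self.drift_slope = drift_slope
        self.sd_ratio = sd_ratio
        self.null_slopes = null
        self.n_null = len(null)
        self.seed = seed
        self.trend_p = rank_p(trend_slope, null["trend"].to_numpy())
        self.drift_p = rank_p(drift_slope, null["drift"].to_numpy())
        self.sd_ratio_p = rank_p(sd_ratio, null["sd_ratio"].to_numpy())

    # --------------------------------------------------------------- verdicts
    def _sd_concordant(self, direction: int) -> bool:
        mode = self.model.sd_concordance
        if mode == "none":
            return True
        if mode == "significance":
            return self.sd_ratio_p < 0.05 if direction > 0 else self.sd_ratio_p > 0.95
        med = float(self.null_slopes["sd_ratio"].median())
        return self.sd_ratio < med if direction > 0 else self.sd_ratio > med

    @property
    def trend_verdict(self) -> str:
        """"+", "-", or "none": rank significance gated by the SD check."""
        if self.trend_p > 0.95 and self._sd_concordant(+1):
            return "+"
        if self.trend_p < 0.05 and self._sd_concordant(-1):
            return "-"
        return "none"

    @property
    def trend_rank_verdict(self) -> str:
        """Rank-only verdict, ignoring the SD gate (sensitivity analysis)."""
        if self.trend_p > 0.95:
            return "+"
        if self.trend_p < 0.05:
            return "-"
        return "none"

    @property
    def drift_verdict(self) -> str:
        if self.drift_p > 0.95:
            return "+"
        if self.drift_p < 0.05:
            return "-"
        return "none"

    # ----------------------------------------------------------------- table
    @property
    def table(self) -> pd.DataFrame:
        """Per-element table: age, rate, logged rescaled rate, phenotype."""
        tree = self.tree
        rate = np.full(tree.n_elements, np.nan)
        rate[1:] = self.ridge.rates.to_numpy()
        resc = np.full(tree.n_elements, np.nan)
        resc[1:] = rescale01(np.abs(self.ridge.rates.to_numpy()))
        phen = self.ridge.predict_phenotype_vector()["phenotype"].to_numpy()
        return pd.DataFrame(
            {
                "age": tree.age,
                "is_tip": tree.is_tip,
                "rate": rate,
                "rate_rescaled": resc,
                "log_rate": np.log(resc + self.model.eps),
                "phenotype": phen,
                "phenotype_rescaled": rescale01(phen),
            },
            index=tree.labels,
        )

    def to_dict(self) -> dict:
        return {
            "trend_slope": self.trend_slope,
            "trend_p": self.trend_p,
            "drift_slope": self.drift_slope,
            "drift_p": self.drift_p,
            "sd_ratio": self.sd_ratio,
            "sd_ratio_p": self.sd_ratio_p,
            "n_null": self.n_null,
            "rootv": self.ridge.rootv,
            "lambda": self.ridge.lam,
            "trend_verdict": self.trend_verdict,
            "drift_verdict": self.drift_verdict,
        }

    def summary(self) -> str:
        d = self.to_dict()
        lines = [
            "Temporal trend search (rank test vs Brownian null families)",
            "=" * 60,
            f"tips: {self.tree.n_tips}   nulls: {self.n_null}   "
            f"rootV: {d['rootv']:.4g}   lambda: {d['lambda']:.3g}",
            "",
            f"rate trend   slope: {d['trend_slope']: .5g}   rank P: {d['trend_p']:.4f}"
            f"   verdict: {d['trend_verdict']}",
            f"  half-tree SD ratio (old/recent): {d['sd_ratio']:.4f}   rank P: {d['sd_ratio_p']:.4f}",
            f"phenotypic drift   slope: {d['drift_slope']: .5g}   rank P: {d['drift_p']:.4f}"
            f"   verdict: {d['drift_verdict']}",
        ]
        return "\n".join(lines)

    def plot(self, axes=None):
        """Trend (left) and drift (right) regressions over the null clouds."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(9, 4))
        tab = self.table
        br = tab[~tab["rate"].isna()]
        axes[0].scatter(br["age"], br["log_rate"], s=10, alpha=0.6, color="seagreen")
        axes[0].set_xlabel("branch age")
        axes[0].set_ylabel("log rescaled |rate|")
        axes[0].set_title(f"trend P = {self.trend_p:.3f}")
        axes[1].scatter(tab["age"], tab["phenotype_rescaled"], s=10, alpha=0.6, color="steelblue")
        axes[1].set_xlabel("element age")
        axes[1].set_ylabel("rescaled phenotype")
        axes[1].set_title(f"drift P = {self.drift_p:.3f}")
        return axes


def search_trend(
    tree: Phylogeny,
    y: pd.Series,
    n_null: int = 100,
    seed: int | None = None,
    **kwargs,
) -> TrendSearchResults:
    """One-call convenience wrapper: ``TrendSearch(tree, y, n_null).fit(seed)``."""
    return TrendSearch(tree, y, n_null=n_null, **kwargs).fit(seed=seed)
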
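"""Normalized phylogenetic ridge regression: per-branch rates and ancestral states.

The model writes each tip phenotype as the root state plus the sum, along the
root-to-tip path, of branch length times a branch-specific rate:

    y_tip = rootV + sum_{branch in path} l_branch * b_branch .

With one rate per branch the system is underdetermined, so the rate vector is
the ridge solution

    b = argmin || (y - rootV) - L b ||^2 + lambda ||b||^2

over the tip rows ``L`` of the path (design) matrix.  Ancestral states at
internal nodes are then read off the node rows: ``rootV + L_node b``.  Rates
are regression coefficients - phenotypic change per unit time between
consecutive nodes - and under Brownian motion their magnitude grows toward
the present, which is the null behavior the trend tests are ranked against.

``rootV`` is estimated from the data as a weighted mean of the 10% most
ancient tips (the earliest-ending lineages), weighted so that older tips
dominate, and is held fixed during the ridge solve.

The penalty ``lambda`` is chosen automatically by minimizing leave-one-out
prediction error of the tip values on a log-spaced grid; the residual is
standardized to unit variance before the solve so the grid is scale-free
(the returned rates are on the original trait scale).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tree import Phylogeny, validate_trait

__all__ = ["PhyloRidge", "PhyloRidgeResults", "RidgeEngine", "estimate_rootv", "build_design_matrix"]

#: scale-free penalty grid searched by the automatic selector
LAMBDA_GRID = np.logspace(-6.0, 3.0, 19)


def build_design_matrix(tree: Phylogeny) -> pd.DataFrame:
    """Path design matrix over all elements (rows) and branches (columns).

    Entry (e, b) is branch b's length if b lies on the root path of element e,
    else 0; row sums equal element ages.  Branch columns are labeled by the
    element below the branch.
    """
    return pd.DataFrame(tree.path_matrix(), index=tree.labels, columns=tree.labels[1:])


def estimate_rootv(
    tree: Phylogeny, y: pd.Series, weighting: str = "inverse_age_sq"
) -> float:
    """Estimate the root phenotype from the most ancient tips.

    The 10% of tips with the smallest age (the earliest-terminating lineages)
    are averaged.  With the default ``inverse_age_sq`` weighting, weights are
    proportional to 1/age^2 so that older tips dominate the estimate; the
    alternative ``age_sq`` weights by age^2 instead.
    """
    y = validate_trait(tree, y)
    ages = tree.age[tree.tip_indices]
    k = max(1, round(0.1 * tree.n_tips))
    sel = np.argsort(ages, kind="stable")[:k]
    w = _rootv_weights(ages[sel], weighting)
    return float(np.average(y.to_numpy()[sel], weights=w))


def _rootv_weights(ages: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "inverse_age_sq":
        return 1.0 / np.square(ages)
    if weighting == "age_sq":
        return np.square(ages)
    raise ValueError("weighting must be 'inverse_age_sq' or 'age_sq'")


class RidgeEngine:
    """Per-tree factorization reused across many trait vectors.

    Holds the SVD of the tip rows of the design matrix so that fitting a new
    trait (or a whole batch of Brownian null traits) costs only matrix-vector
    work.  All traits fitted through one engine share the same penalty policy,
    which is what makes observed and null regression slopes comparable.
    """

    def __init__(self, tree: Phylogeny, lam="auto", rootv_weighting: str = "inverse_age_sq"):
        self.tree = tree
        self.lam = lam
        self.rootv_weighting = rootv_weighting
        L = tree.path_matrix()
        self.L_tip = L[tree.tip_indices]
        self.L_node = L[tree.node_indices]
        self._U, self._s, self._Vt = np.linalg.svd(self.L_tip, full_matrices=False)
        ages = tree.age[tree.tip_indices]
        k = max(1, round(0.1 * tree.n_tips))
        self._rootv_sel = np.argsort(ages, kind="stable")[:k]
        w = _rootv_weights(ages[self._rootv_sel], rootv_weighting)
        self._rootv_w = w / w.sum()

    def rootv(self, Y: np.ndarray) -> np.ndarray:
        """Root estimate per column of a (tips x k) matrix."""
        return self._rootv_w @ Y[self._rootv_sel]

    def fit_batch(self, Y: np.ndarray, root_value=None):
        """Fit every column of ``Y`` (tips x k).

        Returns ``(rates, node_est, fitted, rootv, lam)`` with shapes
        (branches x k), (nodes x k), (tips x k), (k,), (k,).
        """
        Y = np.asarray(Y, dtype=float)
        squeeze = Y.ndim == 1
        if squeeze:
            Y = Y[:, None]
        k = Y.shape[1]
        rootv = np.full(k, float(root_value)) if root_value is not None else self.rootv(Y)
        R = Y - rootv
        scale = R.std(axis=0)
        safe = np.where(scale > 1e-300, scale, 1.0)
        Rs = R / safe
        C = self._U.T @ Rs  # (n_tip x k) projections
        s2 = np.square(self._s)
        if self.lam == "auto":
            lam_idx = np.empty(k, dtype=int)
            press = np.full((LAMBDA_GRID.size, k), np.inf)
            U2 = np.square(self._U)
            for g, lam in enumerate(LAMBDA_GRID):
                d = s2 / (s2 + lam)
                fitted = self._U @ (d[:, None] * C)
                h = U2 @ d
                denom = np.clip(1.0 - h, 1e-10, None)
                e = (Rs - fitted) / denom[:, None]
                press[g] = np.square(e).sum(axis=0)
            lam_idx = press.argmin(axis=0)
            lams = LAMBDA_GRID[lam_idx]
        else:
            lams = np.full(k, float(self.lam))
        B = np.empty((self.L_tip.shape[1], k))
        for lam in np.unique(lams):
            cols = lams == lam
            if lam > 0:
                f = self._s / (s2 + lam)
            else:  # minimum-norm least squares on the nonzero singular space
                f = np.divide(1.0, self._s, out=np.zeros_like(self._s), where=self._s > 1e-12)
            B[:, cols] = self._Vt.T @ (f[:, None] * C[:, cols])
        B *= safe
        node_est = rootv + self.L_node @ B
        fitted = rootv + self.L_tip @ B
        if squeeze:
            return B[:, 0], node_est[:, 0], fitted[:, 0], float(rootv[0]), float(lams[0])
        return B, node_est, fitted, rootv, lams


class PhyloRidge:
    """Phylogenetic ridge regression model for one tree and one trait.

    Parameters
    ----------
    tree : Phylogeny
    y : Series
        Tip-keyed continuous trait.
    lam : "auto" or float
        Ridge penalty; "auto" selects by leave-one-out error on a log grid.
    root_value : float, optional
        Fix the root state instead of estimating it from the oldest tips.
    rootv_weighting : str
        Weighting rule for the root estimate (see :func:`estimate_rootv`).
    """

    def __init__(self, tree: Phylogeny, y: pd.Series, lam="auto",
                 root_value: float | None = None, rootv_weighting: str = "inverse_age_sq"):
        self.tree = tree
        self.y = validate_trait(tree, y)
        self.lam = lam
        self.root_value = root_value
        self.rootv_weighting = rootv_weighting

    @classmethod
    def from_files(cls, tree_path, trait_path, **kwargs) -> "PhyloRidge":
        from .tree import read_newick, read_trait_csv

        with open(tree_path) as fh:
            tree = read_newick(fh.read())
        return cls(tree, read_trait_csv(trait_path), **kwargs)

    def fit(self, engine: RidgeEngine | None = None) -> "PhyloRidgeResults":
        if engine is None:
            engine = RidgeEngine(self.tree, lam=self.lam, rootv_weighting=self.rootv_weighting)
        b, node_est, fitted, rootv, lam = engine.fit_batch(
            self.y.to_numpy(), root_value=self.root_value
        )
        return PhyloRidgeResults(self, engine, b, node_est, fitted, rootv, lam)


class PhyloRidgeResults:
    """Fitted rates, ancestral states, and the root estimate."""

    def __init__(self, model, engine, rates, node_est, fitted, rootv, lam):
        self.model = model
        self.engine = engine
        tree = model.tree
        self.tree = tree
        self.rates = pd.Series(rates, index=tree.labels[1:], name="rate")
        self.node_estimates = pd.Series(
            node_est, index=[tree.labels[i] for i in tree.node_indices], name="estimate"
        )
        self.fittedvalues = pd.Series(fitted, index=tree.tip_labels, name="fitted")
        self.rootv = float(rootv)
        self.lam = float(lam)

    def predict_phenotype_vector(self) -> pd.DataFrame:
        """Ancestral estimates collated with observed tip values, with ages.

        One row per element (nodes then tips is *not* the order; rows follow
        the tree's preorder): columns ``age``, ``is_tip``, ``phenotype`` where
        the phenotype is the node estimate for internal nodes and the observed
        trait for tips.  This is the input of the drift regression.
        """
        tree = self.tree
        phen = np.empty(tree.n_elements)
        phen[tree.node_indices] = self.node_estimates.to_numpy()
        phen[tree.tip_indices] = self.model.y.to_numpy()
        return pd.DataFrame(
            {"age": tree.age, "is_tip": tree.is_tip, "phenotype": phen},
            index=tree.labels,
        )

    def summary(self) -> str:
        r = np.corrcoef(self.fittedvalues, self.model.y)[0, 1]
        lines = [
            "Phylogenetic ridge regression",
            "=" * 45,
            f"tips: {self.tree.n_tips}   nodes: {self.tree.n_nodes}   branches: {self.tree.n_branches}",
            f"rootV: {self.rootv:.6g}   lambda: {self.lam:.3g}",
            f"rate magnitude: mean {np.abs(self.rates).mean():.4g}, max {np.abs(self.rates).max():.4g}",
            f"tip fit correlation: {r:.4f}",
        ]
        return "\n".join(lines)

    def plot_rates(self, ax=None):
        """Scatter of |rate| (log scale) against branch age."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        age = self.tree.age[1:]
        ax.scatter(age, np.abs(self.rates), s=12, alpha=0.6)
        ax.set_yscale("log")
        ax.set_xlabel("branch age (distance from root)")
        ax.set_ylabel("|rate|")
        return ax
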
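"""Clade contrasts: test focal clades against the tree background and each other.

Drift is compared clade-by-clade: the drift regression (rescaled phenotype
against element age) is refit on the clade's own elements, and the observed
clade slope is ranked within the same clade-restricted slope computed on each
Brownian null trait simulated on the full tree.

Rate trends cannot be compared through raw clade slopes, because a clade's
slope depends on where the clade sits relative to the root (rate magnitude
changes nonlinearly with age).  Instead, a single linear model

    log rescaled |rate| ~ age * group

is fitted over all branches, and each group's estimated marginal mean (EMM) -
its adjusted prediction at the grand-mean branch age - is contrasted against
the background or the other clade.  Observed EMM contrasts are ranked within
the same contrast computed on each Brownian null replicate; a parametric
t-test of the contrast from the observed fit is also reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ridge import PhyloRidge, RidgeEngine
from .tree import CladeSelection, InvalidSelectionError, Phylogeny, validate_trait
from .trend import LOG_EPS, rank_p, rescale01, simulate_null_batch, _branch_age

__all__ = ["assign_groups", "CladeContrast", "CladeContrastResults"]


def assign_groups(tree: Phylogeny, clades: list[CladeSelection]) -> pd.Series:
    """Label every element by its enclosing focal clade, else 'background'.

    Clades must be pairwise disjoint; each element gets exactly one label
    (the focal node itself belongs to its clade).
    """
    for i, a in enumerate(clades):
        for b in clades[i + 1:]:
            if a.overlaps(b):
                raise InvalidSelectionError(
                    f"clades {a.node!r} and {b.node!r} overlap"
                )
    labels = np.array(["background"] * tree.n_elements, dtype=object)
    for c in clades:
        labels[c.element_indices] = c.node
    return pd.Series(labels, index=tree.labels, name="group")


def _emm_design(age: np.ndarray, groups: np.ndarray, clade_names: list[str]):
    """Design matrix for log|rate| ~ age * group and the EMM contrast rows.

    Background is the reference level; the interaction is always retained.
    Returns (X, contrasts) where contrasts maps each clade to the row vector
    c with c @ beta = EMM(clade) - EMM(background) at the grand-mean age.
    """
    n = age.size
    abar = age.mean()
    cols = [np.ones(n), age]
    for name in clade_names:
        d = (groups == name).astype(float)
        cols.append(d)
        cols.append(d * age)
    X = np.column_stack(cols)
    contrasts = {}
    for j, name in enumerate(clade_names):
        c = np.zeros(X.shape[1])
        c[2 + 2 * j] = 1.0
        c[3 + 2 * j] = abar
        contrasts[name] = c
    return X, contrasts


class CladeContrast:
    """Model object contrasting one or two clades within a tree.

    Parameters
    ----------
    tree : Phylogeny
    y : Series
        Tip-keyed trait.
    clades : sequence of CladeSelection or node labels
        One or two disjoint focal clades (>= 2 tips each; the validation
        batteries use >= 20).
    n_null : int
        Brownian null family size.
    lam : "auto" or float
        Ridge penalty policy shared with the nulls.
    """

    def __init__(self, tree: Phylogeny, y: pd.Series, clades, n_null: int = 100,
                 lam="auto", age_mode: str = "child", eps: float = LOG_EPS,
                 null_mode: str = "pipeline"):
        self.tree = tree
        self.y = validate_trait(tree, y)
        self.clades = [c if isinstance(c, CladeSelection) else tree.clade(c) for c in clades]
        if not 1 <= len(self.clades) <= 2:
            raise InvalidSelectionError("provide one or two focal clades")
        self.groups = assign_groups(tree, self.clades)
        self.n_null = int(n_null)
        self.lam = lam
        self.age_mode = age_mode
        self.eps = float(eps)
        self.null_mode = null_mode

    # ------------------------------------------------------------ statistics
    def _statistics(self, rates: np.ndarray, node_est: np.ndarray, tips: np.ndarray):
        """Clade drift slopes and EMM contrasts for each column."""
        tree = self.tree
        rates = np.atleast_2d(rates.T).T
        node_est = np.atleast_2d(node_est.T).T
        tips = np.atleast_2d(tips.T).T
        k = rates.shape[1]
        phen = np.empty((tree.n_elements, k))
        phen[tree.node_indices] = node_est
        phen[tree.tip_indices] = tips
        drift = {}
        for c in self.clades:
            sub = phen[c.element_indices]
            a = tree.age[c.element_indices]
            ac = a - a.mean()
            drift[c.node] = ac @ (rescale01(sub) - rescale01(sub).mean(axis=0)) / (ac @ ac)
        log_rates = np.log(rescale01(np.abs(rates)) + self.eps)
        beta, *_ = np.linalg.lstsq(self._X, log_rates, rcond=None)
        emm = {name: c @ beta for name, c in self._contrast_rows.items()}
        pair = None
        if len(self.clades) == 2:
            a, b = (c.node for c in self.clades)
            pair = {"trend": emm[a] - emm[b], "drift": drift[a] - drift[b]}
        return drift, emm, pair

    # ------------------------------------------------------------------- fit
    def fit(self, seed: int | None = None, engine: RidgeEngine | None = None) -> "CladeContrastResults":
        tree = self.tree
        if engine is None:
            engine = RidgeEngine(tree, lam=self.lam)
        b_age = _branch_age(tree, self.age_mode)
        grp = self.groups.to_numpy()[1:]
        self._X, self._contrast_rows = _emm_design(b_age, grp, [c.node for c in self.clades])
        ridge = PhyloRidge(tree, self.y, lam=self.lam).fit(engine=engine)
        obs_drift, obs_emm, obs_pair = self._statistics(
            ridge.rates.to_numpy(), ridge.node_estimates.to_numpy(), self.y.to_numpy()
        )
        rng = np.random.default_rng(seed)
        rates, node_est, tips = simulate_null_batch(
            tree, self.n_null, rng, null_mode=self.null_mode, engine=engine
        )
        null_drift, null_emm, null_pair = self._statistics(rates, node_est, tips)
        return CladeContrastResults(
            self, ridge, obs_drift, obs_emm, obs_pair, null_drift, null_emm, null_pair
        )


class CladeContrastResults:
    """Per-clade drift slopes, trend EMM contrasts, and their rank P values."""

    def __init__(self, model, ridge, obs_drift, obs_emm, obs_pair,
                 null_drift, null_emm, null_pair):
        self.model = model
        self.ridge = ridge
        self.clades = model.clades
        self.groups = model.groups
        self.drift_slope = {k: float(v[0]) for k, v in obs_drift.items()}
        self.trend_emm_contrast = {k: float(v[0]) for k, v in obs_emm.items()}
        self.drift_p = {
            k: rank_p(self.drift_slope[k], null_drift[k]) for k in self.drift_slope
        }
        self.trend_p = {
            k: rank_p(self.trend_emm_contrast[k], null_emm[k])
            for k in self.trend_emm_contrast
        }
        self.null = {"drift": null_drift, "trend_emm": null_emm, "pair": null_pair}
        if obs_pair is not None:
            self.pair_contrast = float(obs_pair["trend"][0])
            self.pair_p = rank_p(self.pair_contrast, null_pair["trend"])
            self.pair_drift_contrast = float(obs_pair["drift"][0])
            self.pair_drift_p = rank_p(self.pair_drift_contrast, null_pair["drift"])
        else:
            self.pair_contrast = None
            self.pair_p = None
            self.pair_drift_contrast = None
            self.pair_drift_p = None
        self._parametric = self._emm_parametric()

    def _emm_parametric(self) -> dict:
        """t-test p-values of the observed EMM contrasts from the linear model."""
        import statsmodels.api as sm

        X = self.model._X
        tab = np.log(
            rescale01(np.abs(self.ridge.rates.to_numpy())) + self.model.eps
        )
        fit = sm.OLS(tab, X).fit()
        out = {}
        for name, c in self.model._contrast_rows.items():
            t = fit.t_test(c)
            out[name] = float(np.squeeze(t.pvalue))
        if len(self.clades) == 2:
            a, b = (c.node for c in self.clades)
            c = self.model._contrast_rows[a] - self.model._contrast_rows[b]
            out[f"{a} vs {b}"] = float(np.squeeze(fit.t_test(c).pvalue))
        return out

    @property
    def parametric_trend_p(self) -> dict:
        return self._parametric

    def verdict(self, kind: str, clade: str | None = None, pairwise: bool = False) -> str:
        """"+", "-", or "none" for a clade's drift/trend departure."""
        if pairwise:
            p = self.pair_p if kind == "trend" else self.pair_drift_p
        elif kind == "drift":
            p = self.drift_p[clade]
        elif kind == "trend":
            p = self.trend_p[clade]
        else:
            raise ValueError("kind must be 'drift' or 'trend'")
        if p is None:
            raise ValueError("no pairwise contrast in a one-clade fit")
        return "+" if p > 0.95 else ("-" if p < 0.05 else "none")

    def to_dict(self) -> dict:
        return {
            "clades": [c.node for c in self.clades],
            "drift_slope": self.drift_slope,
            "drift_p": self.drift_p,
            "trend_emm_contrast": self.trend_emm_contrast,
            "trend_p": self.trend_p,
            "pair_contrast": self.pair_contrast,
            "pair_p": self.pair_p,
            "pair_drift_contrast": self.pair_drift_contrast,
            "pair_drift_p": self.pair_drift_p,
            "parametric_trend_p": self._parametric,
        }

    def summary(self) -> str:
        lines = ["Clade contrasts (rank tests vs Brownian null families)", "=" * 60]
        for c in self.clades:
            lines.append(
                f"clade {c.node} ({c.n_tips} tips, H_ratio {c.h_ratio:.2f}):"
            )
            lines.append(
                f"  drift slope {self.drift_slope[c.node]: .5g}  rank P {self.drift_p[c.node]:.4f}"
                f"  verdict {self.verdict('drift', c.node)}"
            )
            lines.append(
                f"  trend EMM vs background {self.trend_emm_contrast[c.node]: .5g}"
                f"  rank P {self.trend_p[c.node]:.4f}  verdict {self.verdict('trend', c.node)}"
            )
        if self.pair_p is not None:
            lines.append(
                f"pairwise trend EMM contrast {self.pair_contrast: .5g}  rank P {self.pair_p:.4f}"
            )
        return "\n".join(lines)
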
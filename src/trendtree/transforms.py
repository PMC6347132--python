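"""Phenotype transforms imposing rate trends (es) and mean drifts (ds).

A Brownian trait ``y`` on a tree with tip ages ``t`` (distance from the root)
is transformed either as

* trend:  ``y * t**es / t`` - with ``es = 1`` the trait is unchanged; with
  ``es > 1`` phenotypic variance inflates toward the present (an increasing
  rate of evolution) and deflates with ``es < 1``; or
* drift:  ``y + t * ds`` - a linear displacement of the phenotypic mean over
  time, positive or negative with the sign of ``ds``.

Clade-restricted variants double the transform parameter and, for drift,
scale by H_ratio (tree height over clade height) so the imposed displacement
is comparable across clades of different depths.

Two scalar metrics quantify how far a transformed trait departs from Brownian
motion: ``dev`` (drift intensity, in trait standard deviations per unit time)
and ``spread`` (trend intensity, the late/early range ratio normalized by the
same ratio under Brownian motion).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .tree import CladeSelection, Phylogeny, validate_trait
from .simulate import simulate_bm_elements

__all__ = [
    "TransformSpec",
    "apply_trend",
    "apply_drift",
    "apply_clade_trend",
    "apply_clade_drift",
    "apply_trend_elements",
    "apply_drift_elements",
    "pic_sigma2",
    "dev_metric",
    "spread_metric",
]


# ------------------------------------------------------------- whole tree ops

def _check_trend_ages(ages: np.ndarray, es: float) -> None:
    if es < 1 and np.any(ages <= 0):
        raise ValueError("trend transform undefined for tip age 0 with es < 1")


def apply_trend(y: pd.Series, tree: Phylogeny, es: float) -> pd.Series:
    """Impose a rate trend: tip i becomes ``y_i * t_i**es / t_i``."""
    if not np.isfinite(es):
        raise ValueError("es must be finite")
    y = validate_trait(tree, y)
    if es == 1:
        return y.copy()
    t = tree.age[tree.tip_indices]
    _check_trend_ages(t, es)
    return pd.Series(y.to_numpy() * np.power(t, es) / t, index=y.index, name=y.name)


def apply_drift(y: pd.Series, tree: Phylogeny, ds: float) -> pd.Series:
    """Impose a mean drift: tip i becomes ``y_i + t_i * ds``."""
    if not np.isfinite(ds):
        raise ValueError("ds must be finite")
    y = validate_trait(tree, y)
    if ds == 0:
        return y.copy()
    t = tree.age[tree.tip_indices]
    return pd.Series(y.to_numpy() + t * ds, index=y.index, name=y.name)


# --------------------------------------------------------------- clade scoped

def apply_clade_trend(
    y: pd.Series, tree: Phylogeny, clade: CladeSelection, es_sig: float
) -> pd.Series:
    """Trend-transform only the tips of ``clade``, with exponent ``2 * es_sig``."""
    y = validate_trait(tree, y)
    out = y.to_numpy().copy()
    t = tree.age[clade.tip_indices]
    _check_trend_ages(t, 2 * es_sig)
    tip_pos = np.searchsorted(tree.tip_indices, clade.tip_indices)
    out[tip_pos] = out[tip_pos] * np.power(t, 2 * es_sig) / t
    return pd.Series(out, index=y.index, name=y.name)


def apply_clade_drift(
    y: pd.Series, tree: Phylogeny, clade: CladeSelection, ds_sig: float
) -> pd.Series:
    """Drift-transform only the tips of ``clade`` with slope ``2 * ds_sig * H_ratio``."""
    if clade.clade_height <= 0:
        raise ValueError("clade height must be positive")
    y = validate_trait(tree, y)
    out = y.to_numpy().copy()
    t = tree.age[clade.tip_indices]
    tip_pos = np.searchsorted(tree.tip_indices, clade.tip_indices)
    out[tip_pos] = out[tip_pos] + t * 2.0 * ds_sig * clade.h_ratio
    return pd.Series(out, index=y.index, name=y.name)


# ------------------------------------------- element-level (simulation) forms

def apply_trend_elements(values: np.ndarray, tree: Phylogeny, es: float) -> np.ndarray:
    """Trend transform applied at every element using its own age.

    The root (age 0) is left unchanged.  Used when true simulated node values
    are carried through a transform, e.g. for the spread metric.
    """
    v = np.asarray(values, dtype=float).copy()
    a = tree.age
    pos = a > 0
    v[pos] = v[pos] * np.power(a[pos], es) / a[pos]
    return v


def apply_drift_elements(values: np.ndarray, tree: Phylogeny, ds: float) -> np.ndarray:
    """Drift transform applied at every element using its own age."""
    return np.asarray(values, dtype=float) + tree.age * ds


# ----------------------------------------------------------------- metrics

def pic_sigma2(tree: Phylogeny, y: pd.Series) -> tuple[float, float]:
    """Brownian rate and root state by independent contrasts.

    Returns ``(sigma2_hat, root_hat)`` where ``sigma2_hat`` is the mean squared
    standardized contrast and ``root_hat`` the GLS root estimate from the
    pruning pass.  Multifurcations are folded pairwise.
    """
    y = validate_trait(tree, y)
    vals = {int(i): float(v) for i, v in zip(tree.tip_indices, y.to_numpy())}
    lens = {int(i): float(tree.edge_length[i]) for i in range(1, tree.n_elements)}
    lens[0] = 0.0
    contrasts = []
    for i in range(tree.n_elements - 1, -1, -1):
        if tree.is_tip[i]:
            continue
        kids = list(tree.children(i))
        x, v = vals[kids[0]], lens[kids[0]]
        for k in kids[1:]:
            x2, v2 = vals[k], lens[k]
            contrasts.append((x - x2) / np.sqrt(v + v2))
            x = (x / v + x2 / v2) / (1 / v + 1 / v2)
            v = v * v2 / (v + v2)
        vals[i] = x
        lens[i] = lens[i] + v
    sigma2 = float(np.mean(np.square(contrasts))) if contrasts else 0.0
    return sigma2, float(vals[0])


def dev_metric(
    y_original: pd.Series,
    y_drifted: pd.Series,
    tree: Phylogeny,
    root_value: float | None = None,
) -> float:
    """Drift intensity: displacement of the trait mean from the root value,
    in trait standard deviations per unit time.

    ``dev = (mean(y_drifted) - root) / (sd(y_drifted) * tree height)`` where
    ``root`` defaults to the independent-contrasts root estimate of the
    untransformed trait.  Zero in expectation when no drift was applied; odd
    in the drift slope.  When the validation batteries impose a drift of
    ``ds`` trait standard deviations per unit time, dev at the tips works out
    to about ``ds * (mean tip age / tree height)``.
    """
    y0 = validate_trait(tree, y_original)
    y1 = validate_trait(tree, y_drifted)
    sd = float(y1.std(ddof=0))
    if sd <= 0:
        raise ValueError("trait has zero standard deviation; dev undefined")
    if root_value is None:
        _, root = pic_sigma2(tree, y0)
    else:
        root = float(root_value)
    return float((y1.mean() - root) / (sd * tree.tree_height))


def _half_range_ratio(values: np.ndarray, age: np.ndarray, half: float) -> np.ndarray:
    """range(values at age > half) / range(values at age <= half), columnwise."""
    values = np.atleast_2d(values.T).T  # (elements, k)
    late = age > half
    early = ~late
    if not late.any() or not early.any():
        raise ValueError("no elements on one side of half tree height")
    r_late = values[late].max(axis=0) - values[late].min(axis=0)
    r_early = values[early].max(axis=0) - values[early].min(axis=0)
    return r_late / r_early


def spread_metric(
    values,
    tree: Phylogeny,
    n_bm_reference: int = 100,
    seed: int | None = None,
) -> float:
    """Trend intensity: late/early range ratio, normalized by Brownian motion.

    ``values`` holds the (transformed) trait at tree elements: either an array
    in element order (tips and nodes, e.g. true simulated values), or a
    tip-keyed Series, in which case node values are filled in by phylogenetic
    ridge regression.  The statistic is the range of values among elements
    beyond half tree height divided by the range among elements before it,
    divided by the mean of the same ratio over ``n_bm_reference`` Brownian
    simulations on the same tree (the ratio is scale-free, so the reference
    rate is immaterial).  Brownian input gives spread near 1.
    """
    if isinstance(values, pd.Series):
        from .ridge import PhyloRidge

        res = PhyloRidge(tree, values).fit()
        v = np.empty(tree.n_elements)
        v[tree.tip_indices] = validate_trait(tree, values).to_numpy()
        v[tree.node_indices] = res.node_estimates.to_numpy()
    else:
        v = np.asarray(values, dtype=float)
        if v.shape != (tree.n_elements,):
            raise ValueError("element values must have one entry per tree element")
    half = tree.tree_height / 2.0
    r_obs = float(_half_range_ratio(v, tree.age, half)[0])
    rng = np.random.default_rng(seed)
    bm = simulate_bm_elements(tree, n_bm_reference, sigma2=1.0, rng=rng)
    r_ref = float(_half_range_ratio(bm, tree.age, half).mean())
    return r_obs / r_ref


# ------------------------------------------------------------------- spec

@dataclass
class TransformSpec:
    """Record of an applied transform, serializable alongside outputs."""

    mode: str  # "trend" | "drift"
    parameter: float
    scope: list[str] | None = None  # clade focal node labels, None = whole tree
    dev: float | None = None
    spread: float | None = None

    def __post_init__(self):
        if self.mode not in ("trend", "drift"):
            raise ValueError("mode must be 'trend' or 'drift'")
        if not np.isfinite(self.parameter):
            raise ValueError("transform parameter must be finite")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)
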
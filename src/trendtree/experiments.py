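"""Simulation batteries: Type I error, power, significance thresholds, clade tests.

Every battery follows the same replicate recipe: simulate a birth-death tree
(birth 0.5, death 0.2, extinct tips retained, >= 80 tips), simulate a
Brownian trait on it (root ~ U(-10, 10), rate from the 300-value grid on
[0.01, 10]), optionally transform the trait (es / ds, whole tree or clade),
run the trend/drift search with 100 Brownian null slopes, and record the rank
probabilities and verdicts.  All randomness derives from one master seed via
spawned child streams, so batteries are exactly reproducible and every
replicate's own seed is logged in the output table.

Drift intensities are specified in units of the untransformed trait's tip
standard deviation per unit time: a battery at ``ds`` applies
``y + times * ds * sd(y)``.  This keeps the imposed drift comparable across
replicates whose Brownian rates span three orders of magnitude (a fixed
absolute slope would be an enormous drift on a quiet trait and an invisible
one on a volatile trait) and pins the realized dev statistic at
``ds * mean tip age / tree height``, independent of the Brownian rate, which
also removes any dependence of the tests' power on the starting rate.  Trend
exponents act multiplicatively and are scale-free as stated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contrast import CladeContrast
from .ridge import RidgeEngine
from .simulate import SIGMA2_GRID, simulate_bd_tree, simulate_bm_elements
from .transforms import (
    apply_clade_drift,
    apply_clade_trend,
    apply_drift,
    apply_trend,
    apply_drift_elements,
    apply_trend_elements,
    dev_metric,
    spread_metric,
)
from .tree import Phylogeny
from .trend import TrendSearch

__all__ = [
    "ES_SIG",
    "DS_SIG",
    "replicate_seeds",
    "standard_replicate",
    "run_table1",
    "run_clade_battery",
    "run_table2",
    "estimate_sig_thresholds",
    "run_size_and_sigma_checks",
    "pick_random_clade",
    "pick_two_clades",
]

#: transform values at which the whole-tree tests reach significance
#: (negative / positive trend exponent, drift slope magnitude)
ES_SIG = (0.3, 1.6)
DS_SIG = 0.25


def replicate_seeds(master_seed: int, n: int, salt: int = 0) -> list[int]:
    """Derive ``n`` independent 31-bit replicate seeds from a master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(salt)])
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def standard_replicate(seed: int, min_tips: int = 80):
    """One tree + Brownian trait draw under the standard battery conditions.

    Returns ``(tree, values, params)`` where ``values`` holds the true trait
    at every element (row order = tree preorder) and ``params`` records the
    root value and Brownian rate used.
    """
    rng = np.random.default_rng(seed)
    tree_seed = int(rng.integers(2**31))
    tree = simulate_bd_tree(min_tips=min_tips, seed=tree_seed)
    root_value = float(rng.uniform(-10, 10))
    sigma2 = float(rng.choice(SIGMA2_GRID))
    values = simulate_bm_elements(tree, 1, sigma2=sigma2, root_value=root_value, rng=rng)[:, 0]
    return tree, values, {"root_value": root_value, "sigma2": sigma2, "tree_seed": tree_seed}


def _tips(tree: Phylogeny, values: np.ndarray) -> pd.Series:
    return pd.Series(values[tree.tip_indices], index=tree.tip_labels, name="value")


# ------------------------------------------------------------------ Table 1

_TABLE1_SCENARIOS = ("BM", "Trend+", "Trend-", "Drift+", "Drift-")


def _transform_for_scenario(scenario, tree, values, es_sig=ES_SIG, ds_sig=DS_SIG):
    """Whole-tree transform of a replicate's element values; returns
    (transformed element values, expected verdict kind, expected sign).

    Drift slopes are in units of the trait's tip standard deviation per unit
    time (see the module docstring).
    """
    if scenario == "BM":
        return values, None, "none"
    if scenario == "Trend+":
        return apply_trend_elements(values, tree, es_sig[1]), "trend", "+"
    if scenario == "Trend-":
        return apply_trend_elements(values, tree, es_sig[0]), "trend", "-"
    sd = float(values[tree.tip_indices].std())
    if scenario == "Drift+":
        return apply_drift_elements(values, tree, ds_sig * sd), "drift", "+"
    if scenario == "Drift-":
        return apply_drift_elements(values, tree, -ds_sig * sd), "drift", "-"
    raise ValueError(f"unknown scenario {scenario!r}")


@dataclass
class BatteryResult:
    """Replicate table plus scenario-level detection frequencies."""

    replicates: pd.DataFrame
    summary: pd.DataFrame
    config: dict = field(default_factory=dict)


def run_table1(
    n_trees: int = 200,
    n_null: int = 100,
    seed: int = 0,
    scenarios=_TABLE1_SCENARIOS,
    es_sig=ES_SIG,
    ds_sig: float = DS_SIG,
    metrics: bool = False,
    **search_kwargs,
) -> BatteryResult:
    """Type I error and power of the whole-tree tests.

    Each scenario reuses the same ``n_trees`` tree/trait replicates (paired
    across scenarios).  ``detected`` means the matched-direction verdict: for
    BM, a trend (resp. drift) verdict of "none" counts as correct; for
    transformed scenarios the verdict must match the imposed sign.
    """
    rows = []
    seeds = replicate_seeds(seed, n_trees, salt=1)
    for rep, rseed in enumerate(seeds):
        tree, values, params = standard_replicate(rseed)
        rng = np.random.default_rng([rseed, 7])
        null_seed = int(rng.integers(2**31))
        engine = None
        null = None
        for scenario in scenarios:
            tvalues, kind, sign = _transform_for_scenario(
                scenario, tree, values, es_sig=es_sig, ds_sig=ds_sig
            )
            y = _tips(tree, tvalues)
            model = TrendSearch(tree, y, n_null=n_null, **search_kwargs)
            if engine is None:
                engine = RidgeEngine(tree, lam=model.lam)
            if null is None:
                null = model.bm_null_slopes(seed=null_seed, engine=engine)
            res = model.fit(seed=null_seed, engine=engine, null=null)
            row = {
                "scenario": scenario,
                "replicate": rep,
                "seed": rseed,
                "n_tips": tree.n_tips,
                "tree_height": tree.tree_height,
                **params,
                "trend_p": res.trend_p,
                "drift_p": res.drift_p,
                "sd_ratio": res.sd_ratio,
                "sd_ratio_p": res.sd_ratio_p,
                "trend_verdict": res.trend_verdict,
                "trend_rank_verdict": res.trend_rank_verdict,
                "drift_verdict": res.drift_verdict,
            }
            row["detected"] = _matched(row, kind, sign)
            row["detected_rank_only"] = _matched(row, kind, sign, rank_only=True)
            if kind is None:
                row["bm_drift_correct"] = row["drift_verdict"] == "none"
            if metrics:
                if scenario.startswith("Drift"):
                    row["dev"] = dev_metric(
                        _tips(tree, values), y, tree, root_value=params["root_value"]
                    )
                if scenario.startswith("Trend"):
                    row["spread"] = spread_metric(tvalues, tree, seed=null_seed)
            rows.append(row)
    reps = pd.DataFrame(rows)
    summary = (
        reps.groupby("scenario", sort=False)[["detected", "detected_rank_only"]]
        .mean()
        .rename(columns={"detected": "frequency", "detected_rank_only": "frequency_rank_only"})
    )
    cfg = {"n_trees": n_trees, "n_null": n_null, "seed": seed,
           "es_sig": list(es_sig), "ds_sig": ds_sig}
    return BatteryResult(reps, summary, cfg)


def _matched(row: dict, kind, sign, rank_only: bool = False) -> bool:
    trend = row["trend_rank_verdict"] if rank_only else row["trend_verdict"]
    if kind is None:  # BM: the trend test is correct when it flags nothing
        return trend == "none"
    if kind == "trend":
        return trend == sign
    return row["drift_verdict"] == sign


# -------------------------------------------------------------- thresholds

@dataclass
class ThresholdResult:
    es_sig_minus: float
    es_sig_plus: float
    ds_sig_minus: float
    ds_sig_plus: float
    replicates: pd.DataFrame
    fits: dict
    config: dict


def estimate_sig_thresholds(
    n_trees: int = 200,
    n_null: int = 100,
    seed: int = 0,
    **search_kwargs,
) -> ThresholdResult:
    """Find the transform values at which the rank tests reach significance.

    On each replicate both a trend-transformed (es ~ U(-1, 3)) and a
    drift-transformed (ds ~ U(-2, 2), in trait-SD units) version of the same
    Brownian trait are tested.  The recorded rank probabilities are regressed
    on the transform parameter with a logistic curve (rank P is a saturating
    function of the transform intensity, so a straight line cannot represent
    it across the sweep range), and the fitted curve is solved for P = 0.05
    and P = 0.95; the straight-line fit is reported alongside as a
    diagnostic.
    """
    rows = []
    seeds = replicate_seeds(seed, n_trees, salt=2)
    for rep, rseed in enumerate(seeds):
        tree, values, params = standard_replicate(rseed)
        rng = np.random.default_rng([rseed, 11])
        es = float(rng.uniform(-1, 3))
        ds = float(rng.uniform(-2, 2))
        null_seed = int(rng.integers(2**31))
        model = TrendSearch(tree, _tips(tree, values), n_null=n_null, **search_kwargs)
        engine = RidgeEngine(tree, lam=model.lam)
        null = model.bm_null_slopes(seed=null_seed, engine=engine)
        sd = float(values[tree.tip_indices].std())
        y_tr = _tips(tree, apply_trend_elements(values, tree, es))
        y_dr = _tips(tree, apply_drift_elements(values, tree, ds * sd))
        res_tr = TrendSearch(tree, y_tr, n_null=n_null, **search_kwargs).fit(
            seed=null_seed, engine=engine, null=null
        )
        res_dr = TrendSearch(tree, y_dr, n_null=n_null, **search_kwargs).fit(
            seed=null_seed, engine=engine, null=null
        )
        rows.append(
            {
                "replicate": rep,
                "seed": rseed,
                "n_tips": tree.n_tips,
                **params,
                "es": es,
                "ds": ds,
                "trend_p": res_tr.trend_p,
                "drift_p": res_dr.drift_p,
            }
        )
    reps = pd.DataFrame(rows)
    fits = {}
    out = {}
    for name, (x, p) in {
        "es": (reps["es"], reps["trend_p"]),
        "ds": (reps["ds"], reps["drift_p"]),
    }.items():
        lo, hi, pars = _logistic_crossings(x.to_numpy(), p.to_numpy())
        b, a = np.polyfit(x.to_numpy(), p.to_numpy(), 1)
        fits[name] = {
            "logistic": pars,
            "linear": {"intercept": float(a), "slope": float(b)},
        }
        out[f"{name}_sig_minus"], out[f"{name}_sig_plus"] = lo, hi
    cfg = {"n_trees": n_trees, "n_null": n_null, "seed": seed}
    return ThresholdResult(
        out["es_sig_minus"], out["es_sig_plus"], out["ds_sig_minus"], out["ds_sig_plus"],
        reps, fits, cfg,
    )


def _logistic_crossings(x: np.ndarray, p: np.ndarray):
    """Fit P(x) = 1 / (1 + exp(-(a + b x))) and solve for P = 0.05 / 0.95.

    Least-squares on the rank probabilities themselves (they are continuous
    on (0, 1)).  Returns (x at P=0.05, x at P=0.95, fit parameters); NaNs when
    the fit fails or is non-increasing.
    """
    from scipy.optimize import curve_fit

    def f(x, a, b):
        return 1.0 / (1.0 + np.exp(-(a + b * x)))

    q = np.clip(p, 1e-4, 1 - 1e-4)
    b0 = 1.0 if np.corrcoef(x, p)[0, 1] >= 0 else -1.0
    a0 = float(np.log(q.mean() / (1 - q.mean())) - b0 * x.mean())
    try:
        (a, b), _ = curve_fit(f, x, p, p0=(a0, b0), maxfev=10000)
    except Exception:
        return float("nan"), float("nan"), {"a": float("nan"), "b": float("nan")}
    if not np.isfinite(b) or b <= 0:
        return float("nan"), float("nan"), {"a": float(a), "b": float(b)}
    logit = lambda t: np.log(t / (1 - t))
    return (
        float((logit(0.05) - a) / b),
        float((logit(0.95) - a) / b),
        {"a": float(a), "b": float(b)},
    )


# ---------------------------------------------- size / sigma^2 diagnostics

def run_size_and_sigma_checks(replicates: pd.DataFrame, p_col: str = "trend_p") -> pd.DataFrame:
    """Regress rank probabilities on tree size and on the Brownian rate.

    Returns one row per predictor with slope, p-value, and R^2; under a
    well-behaved test neither tree size nor sigma^2 should predict P.
    """
    import statsmodels.api as sm

    rows = []
    for pred in ("n_tips", "sigma2"):
        if pred not in replicates:
            continue
        X = sm.add_constant(replicates[pred].to_numpy(float))
        fit = sm.OLS(replicates[p_col].to_numpy(float), X).fit()
        rows.append(
            {
                "predictor": pred,
                "response": p_col,
                "slope": float(fit.params[1]),
                "p_value": float(fit.pvalues[1]),
                "r_squared": float(fit.rsquared),
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ Table 2

def pick_random_clade(
    tree: Phylogeny,
    rng: np.random.Generator,
    min_tips: int = 20,
    min_background_tips: int = 20,
):
    """Uniformly pick an internal (non-root) node subtending >= ``min_tips``
    tips while leaving >= ``min_background_tips`` outside it."""
    cands = []
    for i in tree.node_indices:
        if i == 0:
            continue
        c = tree.clade(int(i))
        if c.n_tips >= min_tips and tree.n_tips - c.n_tips >= min_background_tips:
            cands.append(c)
    if not cands:
        return None
    return cands[int(rng.integers(len(cands)))]


def pick_two_clades(tree: Phylogeny, rng: np.random.Generator, min_tips: int = 20,
                    max_tries: int = 200):
    """Pick two disjoint clades with >= ``min_tips`` tips each."""
    cands = [
        tree.clade(int(i))
        for i in tree.node_indices
        if i != 0 and tree.clade(int(i)).n_tips >= min_tips
    ]
    if len(cands) < 2:
        return None
    for _ in range(max_tries):
        i, j = rng.integers(len(cands)), rng.integers(len(cands))
        if i == j:
            continue
        a, b = cands[int(i)], cands[int(j)]
        if not a.overlaps(b):
            return a, b
    return None


def _clade_transform(kind, sign, y, tree, clade, sd, es_sig=ES_SIG, ds_sig=DS_SIG):
    """Clade transform; drift slopes are in trait-SD units (x ``sd``)."""
    if kind == "bm":
        return y
    if kind == "trend":
        return apply_clade_trend(y, tree, clade, es_sig[1] if sign == "+" else es_sig[0])
    if kind == "drift":
        d = ds_sig * sd
        return apply_clade_drift(y, tree, clade, d if sign == "+" else -d)
    raise ValueError(kind)


def run_clade_battery(
    kind: str,
    n_trees: int = 50,
    n_null: int = 100,
    seed: int = 0,
    two_clades: bool = False,
    signs: str = "random",
    min_clade_tips: int = 20,
    es_sig=ES_SIG,
    ds_sig: float = DS_SIG,
    test: str | None = None,
    **contrast_kwargs,
) -> BatteryResult:
    """Clade-contrast battery for one scenario.

    Parameters
    ----------
    kind : {"trend", "drift", "bm"}
        What is imposed on the focal clade(s); "bm" leaves them untouched
        (Type I error battery).
    two_clades : bool
        Transform and test two disjoint clades instead of one.
    signs : {"random", "positive", "negative", "same", "opposite"}
        Sign policy of the transform(s).  "same"/"opposite" apply to
        two-clade runs; "random" draws each sign independently.
    test : {"trend", "drift"}, optional
        Which contrast to score; defaults to ``kind`` (must be given
        explicitly for a "bm" battery).
    """
    if kind not in ("trend", "drift", "bm"):
        raise ValueError("kind must be trend|drift|bm")
    if test is None:
        if kind == "bm":
            raise ValueError("a 'bm' battery needs an explicit test= to score")
        test = kind
    if test not in ("trend", "drift"):
        raise ValueError("test must be trend|drift")
    rows = []
    seeds = replicate_seeds(seed, n_trees, salt=3 if not two_clades else 4)
    for rep, rseed in enumerate(seeds):
        tree, values, params = standard_replicate(rseed)
        rng = np.random.default_rng([rseed, 13])
        null_seed = int(rng.integers(2**31))
        if two_clades:
            pair = pick_two_clades(tree, rng, min_tips=min_clade_tips)
            if pair is None:
                continue
            clades = list(pair)
        else:
            c = pick_random_clade(tree, rng, min_tips=min_clade_tips)
            if c is None:
                continue
            clades = [c]
        s = _draw_signs(signs, len(clades), rng)
        y = _tips(tree, values)
        sd = float(y.std(ddof=0))
        for clade, sign in zip(clades, s):
            y = _clade_transform(kind, sign, y, tree, clade, sd, es_sig=es_sig, ds_sig=ds_sig)
        res = CladeContrast(
            tree, y, clades, n_null=n_null, **contrast_kwargs
        ).fit(seed=null_seed)
        row = {
            "replicate": rep,
            "seed": rseed,
            "n_tips": tree.n_tips,
            **params,
            "kind": kind,
            "signs": "".join(s),
            "clades": "|".join(c.node for c in clades),
            "clade_tips": "|".join(str(c.n_tips) for c in clades),
            "h_ratio": "|".join(f"{c.h_ratio:.3f}" for c in clades),
        }
        for clade, sign in zip(clades, s):
            v = res.verdict(test, clade.node)
            row[f"detected_{clade.node}"] = (v != "none") if kind == "bm" else (v == sign)
            row[f"p_{clade.node}"] = (
                res.trend_p[clade.node] if test == "trend" else res.drift_p[clade.node]
            )
        row["detected_individual"] = all(
            row[f"detected_{c.node}"] for c in clades
        ) if kind != "bm" else any(row[f"detected_{c.node}"] for c in clades)
        if two_clades:
            pv = res.verdict(test, pairwise=True)
            row["pair_detected"] = pv != "none"
            row["pair_p"] = res.pair_p if test == "trend" else res.pair_drift_p
        rows.append(row)
    reps = pd.DataFrame(rows)
    agg = {"detected_individual": "mean"}
    if two_clades:
        agg["pair_detected"] = "mean"
    summary = reps.agg(agg).to_frame(name="frequency") if len(reps) else pd.DataFrame()
    cfg = {
        "kind": kind, "n_trees": n_trees, "n_null": n_null, "seed": seed,
        "two_clades": two_clades, "signs": signs, "min_clade_tips": min_clade_tips,
    }
    return BatteryResult(reps, summary, cfg)


def _draw_signs(policy: str, k: int, rng: np.random.Generator) -> list[str]:
    if policy == "positive":
        return ["+"] * k
    if policy == "negative":
        return ["-"] * k
    if policy == "same":
        s = "+" if rng.random() < 0.5 else "-"
        return [s] * k
    if policy == "opposite":
        if k != 2:
            raise ValueError("'opposite' requires two clades")
        return ["+", "-"] if rng.random() < 0.5 else ["-", "+"]
    if policy == "random":
        return ["+" if rng.random() < 0.5 else "-" for _ in range(k)]
    raise ValueError(f"unknown sign policy {policy!r}")


def run_table2(n_trees: int = 50, n_null: int = 100, seed: int = 0, **kwargs) -> pd.DataFrame:
    """Detection frequencies across the clade scenarios (one clade; two
    clades individually; two clades against each other, same/opposite sign)."""
    rows = []
    for kind in ("bm", "trend", "drift"):
        tests = ("trend", "drift") if kind == "bm" else (kind,)
        for test in tests:
            one = run_clade_battery(
                kind, n_trees=n_trees, n_null=n_null, seed=seed, test=test, **kwargs
            )
            rows.append({"scenario": kind, "test": test, "mode": "one_clade",
                         "frequency": one.replicates["detected_individual"].mean()})
            for signs in ("opposite", "same"):
                if kind == "bm" and signs == "same":
                    continue
                two = run_clade_battery(
                    kind, n_trees=n_trees, n_null=n_null, seed=seed, test=test,
                    two_clades=True, signs=signs if kind != "bm" else "random", **kwargs
                )
                rows.append({"scenario": kind, "test": test, "mode": f"two_clades_{signs}",
                             "frequency": two.replicates["pair_detected"].mean()})
                rows.append({"scenario": kind, "test": test,
                             "mode": f"two_clades_individual_{signs}",
                             "frequency": two.replicates["detected_individual"].mean()})
    return pd.DataFrame(rows)
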
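"""Simulators for the validation harness: birth-death trees and Brownian traits.

The defaults reproduce the validation conditions used throughout the package:
birth rate 0.5, death rate 0.2, extinct lineages retained as fossil tips
(so trees are non-ultrametric), trees rejected below 80 tips; Brownian traits
with root value ~ U(-10, 10) and rate sigma^2 drawn from a 300-point uniform
grid on [0.01, 10]; trend exponents es ~ U(-1, 3) and drift slopes
ds ~ U(-2, 2).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .tree import Phylogeny

__all__ = [
    "SimulationFailure",
    "simulate_bd_tree",
    "simulate_bm",
    "simulate_bm_elements",
    "draw_experiment_params",
    "ExperimentParams",
]

#: grid the Brownian rate is drawn from (300 equally spaced values on [0.01, 10])
SIGMA2_GRID = np.linspace(0.01, 10.0, 300)


class SimulationFailure(RuntimeError):
    """Raised when the tree simulator cannot satisfy the size condition."""


def simulate_bd_tree(
    birth: float = 0.5,
    death: float = 0.2,
    min_tips: int = 80,
    seed: int | None = None,
    num_extant: int = 100,
    max_attempts: int = 100,
) -> Phylogeny:
    """Simulate a birth-death tree, keeping extinct lineages as tips.

    The process runs until ``num_extant`` lineages are alive; extinct tips are
    retained, so the returned tree is non-ultrametric whenever ``death > 0``.
    Trees with fewer than ``min_tips`` total tips are rejected and redrawn.

    With the defaults (birth 0.5, death 0.2, 100 extant) total tip counts
    average about 160 and essentially never fall below 80.
    """
    if not birth > death >= 0:
        raise ValueError("require birth > death >= 0")
    rng = random.Random(None if seed is None else int(seed))
    for attempt in range(1, max_attempts + 1):
        dtree = treesim.birth_death_tree(
            birth_rate=birth,
            death_rate=death,
            num_extant_tips=num_extant,
            is_retain_extinct_tips=True,
            rng=rng,
        )
        # The process stops exactly at the num_extant-th birth, leaving that
        # event's two daughters with zero-length edges.  Run the process for
        # the waiting time to the next event (nothing happens during it) by
        # extending every extant tip by one Exp(n * (birth + death)) draw.
        dtree.calc_node_root_distances()
        leaves = dtree.leaf_nodes()
        height = max(nd.root_distance for nd in leaves)
        extra = rng.expovariate(num_extant * (birth + death))
        for nd in leaves:
            if nd.root_distance >= height - 1e-9:
                nd.edge.length += extra
        tree = Phylogeny.from_dendropy(dtree)
        if tree.n_tips >= min_tips:
            return tree
    raise SimulationFailure(
        f"no tree with >= {min_tips} tips in {max_attempts} attempts "
        f"(birth={birth}, death={death}, num_extant={num_extant})"
    )


def simulate_bm_elements(
    tree: Phylogeny,
    n_sims: int,
    sigma2: float = 1.0,
    root_value: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate ``n_sims`` Brownian traits at every element of the tree.

    Returns an array of shape (n_elements, n_sims) in the tree's preorder
    element order (row 0 is the root, equal to ``root_value``).  Increments are
    independent Gaussians with variance ``sigma2 * branch_length``.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    sd = np.sqrt(sigma2 * tree.edge_length[1:])
    eps = rng.standard_normal((tree.n_branches, n_sims)) * sd[:, None]
    return root_value + tree.path_indicator() @ eps


def simulate_bm(
    tree: Phylogeny,
    sigma2: float,
    root_value: float = 0.0,
    seed: int | None = None,
    include_nodes: bool = False,
):
    """Simulate one Brownian-motion trait on a tree.

    Returns a tip-keyed Series; with ``include_nodes=True`` also returns the
    true values at internal nodes (a second, node-keyed Series).
    """
    rng = np.random.default_rng(seed)
    vals = simulate_bm_elements(tree, 1, sigma2=sigma2, root_value=root_value, rng=rng)[:, 0]
    tips = pd.Series(vals[tree.tip_indices], index=tree.tip_labels, name="value")
    if include_nodes:
        nodes = pd.Series(
            vals[tree.node_indices],
            index=[tree.labels[i] for i in tree.node_indices],
            name="value",
        )
        return tips, nodes
    return tips


@dataclass
class ExperimentParams:
    """One replicate's draw of Brownian and transform parameters."""

    root_value: float
    sigma2: float
    es: float
    ds: float
    seed: int


def draw_experiment_params(seed: int) -> ExperimentParams:
    """Draw one replicate's parameters.

    root_value ~ U(-10, 10); sigma2 uniform over the 300-value grid on
    [0.01, 10]; es ~ U(-1, 3); ds ~ U(-2, 2).  The same seed always returns
    the same draw.
    """
    rng = np.random.default_rng(seed)
    return ExperimentParams(
        root_value=float(rng.uniform(-10, 10)),
        sigma2=float(rng.choice(SIGMA2_GRID)),
        es=float(rng.uniform(-1, 3)),
        ds=float(rng.uniform(-2, 2)),
        seed=int(seed),
    )
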
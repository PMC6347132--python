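import numpy as np
import pytest

import trendtree as tt


@pytest.fixture(scope="session")
def toy_tree():
    """Five-tip hand-checkable tree with one extinct tip (D ends early)."""
    return tt.read_newick("(((A:1.0,B:1.5):1.0,(C:2.0,D:0.5):0.5):1.0,E:3.5);")


@pytest.fixture(scope="session")
def bd_tree():
    """One standard-conditions birth-death tree (fixed seed)."""
    return tt.simulate_bd_tree(seed=1234)


@pytest.fixture(scope="session")
def small_bd_tree():
    """Smaller birth-death tree for heavier Monte Carlo loops."""
    return tt.simulate_bd_tree(min_tips=30, num_extant=25, seed=99)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_trees(n, seed=0, num_extant=40, min_tips=20):
    """Batch of small random birth-death trees for property checks."""
    seeds = np.random.SeedSequence(seed).spawn(n)
    return [
        tt.simulate_bd_tree(
            min_tips=min_tips, num_extant=num_extant,
            seed=int(s.generate_state(1)[0] % 2**31),
        )
        for s in seeds
    ]
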
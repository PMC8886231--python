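import numpy as np
import pytest

from climniche.simulate import SimulationConfig, simulate_tree
from climniche.tree import Chronogram, parse_newick


def random_chronogram(seed: int, n_tips: int) -> Chronogram:
    """Random ultrametric birth-death tree for oracle comparisons."""
    return simulate_tree(
        SimulationConfig(n_tips=n_tips, root_age=float(5 + (seed % 7)), seed=seed)
    )


def mrca_depth_bruteforce(tree: Chronogram, i: int, j: int) -> float:
    """Root-to-MRCA path length by explicit path enumeration."""

    def path(v):
        out = []
        while v >= 0:
            out.append(v)
            v = tree.parent[v]
        return out

    common = set(path(i)) & set(path(j))
    return max(tree.depths[v] for v in common)


@pytest.fixture(scope="session")
def tree81() -> Chronogram:
    """An 81-tip, 100-Myr chronogram shared by the simulation-heavy tests."""
    return simulate_tree(SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def cov81(tree81):
    return tree81.phylo_covariance().C


@pytest.fixture
def balanced4() -> Chronogram:
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def cherry() -> Chronogram:
    return parse_newick("(A:1,B:1);")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
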
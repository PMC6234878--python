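import numpy as np
import pytest
from hypothesis import settings

from nichevol import synth
from nichevol.tree import PhyloTree

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cherry_tree():
    return PhyloTree.from_newick("(A:1,B:1);")


@pytest.fixture(scope="session")
def three_tip_tree():
    return PhyloTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def bd_tree20():
    """A 20-tip ultrametric birth–death tree reused across modules."""
    return synth.simulate_bd_tree(1.0, 0.2, 20, seed=2024)


@pytest.fixture(scope="session")
def random_trees():
    """Small random ultrametric trees with varying tip counts."""
    return [synth.simulate_bd_tree(1.0, 0.1, n, seed=100 + n)
            for n in (5, 8, 12, 20)]


def er_matrix(k: float, rate: float) -> np.ndarray:
    Q = np.full((k, k), rate)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


@pytest.fixture(scope="session")
def er2():
    return er_matrix(2, 0.5)
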
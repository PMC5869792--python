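import numpy as np
import pytest

from hmtree.go_graph import GoTree, load_dag, transform_to_tree, transitive_reduce
from hmtree.model import HmtmParams

# A four-node diamond: the root, two overlapping children, and a shared
# grandchild with two parents (the classic multi-parent case).  The second
# parent is given one extra gene so the larger-parent retention rule keeps
# the grandchild under it.
FIG4_EDGES = [
    ("n1", "n2"),
    ("n1", "n3"),
    ("n1", "n4"),  # redundant: n1 -> n2/n3 -> n4
    ("n2", "n4"),
    ("n3", "n4"),
]
FIG4_ANNOTATIONS = [
    ("g1", "n1"),
    ("g2", "n2"),
    ("g3", "n3"),
    ("g3b", "n3"),
    ("g4a", "n4"),
    ("g4b", "n4"),
]


@pytest.fixture(scope="session")
def fig4_dag():
    return load_dag(FIG4_EDGES, FIG4_ANNOTATIONS)


@pytest.fixture(scope="session")
def fig4_tree(fig4_dag):
    return transform_to_tree(transitive_reduce(fig4_dag))


def make_tree(parent: list[int]) -> GoTree:
    """A GoTree from a parent vector (parent[0] == -1), with placeholder
    gene sets for tests that only exercise the probabilistic machinery."""
    n = len(parent)
    return GoTree(
        ids=[f"t{i:03d}" for i in range(n)],
        parent=np.asarray(parent),
        gene_sets=[frozenset({"g"})] * n,
    )


def random_tree(rng: np.random.Generator, n: int) -> GoTree:
    """Random rooted tree on n nodes; parents always precede children."""
    parent = [-1] + [int(rng.integers(0, i)) for i in range(1, n)]
    return make_tree(parent)


def random_theta(rng: np.random.Generator) -> HmtmParams:
    """A random parameter vector drawn from the interior of every box."""
    return HmtmParams(
        pi=rng.uniform(0.1, 0.9),
        omega=rng.uniform(0.1, 0.9),
        alpha=rng.uniform(0.1, 1.0),
        beta=rng.uniform(1.5, 15.0),
        lam=rng.uniform(0.3, 1.0),
        alpha0=rng.uniform(1.2, 4.0),
        beta0=rng.uniform(1.2, 4.0),
    )


def random_instance(rng: np.random.Generator, max_nodes: int = 12):
    """(tree, p-values, theta) for oracle-equivalence tests."""
    n = int(rng.integers(1, max_nodes + 1))
    tree = random_tree(rng, n)
    theta = random_theta(rng)
    pvals = rng.uniform(0.001, 0.999, size=n)
    return tree, pvals, theta
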
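"""Synthetic data with the model's statistical structure, plus brute-force
enumeration oracles.

The generator builds a rooted DAG the way GO looks locally — a random tree
backbone with a fraction of nodes receiving an extra parent — assigns genes
to leaf terms and propagates them upward, simulates logically consistent
hidden states down the tree (a null parent forces null children), and draws
p-values from the state-dependent emission densities.

The enumeration oracles compute likelihoods and posteriors exactly by
summing over all logically consistent state configurations (the up-closed
1-sets: on a path of n nodes there are exactly n + 1 of them).  They are
deliberately independent of the recursive algorithms they validate and are
capped at 20 tree nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .go_graph import DagTreeMap, GoDag, GoTree, load_dag, transform_to_tree, transitive_reduce
from .model import HmtmParams, clip_pvalues, emission_matrix, validate_params

__all__ = [
    "SimConfig",
    "SimData",
    "random_dag",
    "simulate_states",
    "simulate_pvalues",
    "simulate_dataset",
    "brute_force_likelihood",
    "brute_force_posteriors",
]

_ENUM_CAP = 20


@dataclass
class SimConfig:
    """Synthetic-study conditions.  ``seed`` is mandatory: every draw flows
    from it and runs are bit-reproducible."""

    theta: HmtmParams
    seed: int
    n_dag_nodes: int = 2000
    n_genes: int = 6000
    max_children: int = 4
    multi_parent_fraction: float = 0.15

    def __post_init__(self) -> None:
        validate_params(self.theta)
        if self.n_dag_nodes < 1 or self.n_genes < 1 or self.max_children < 1:
            raise InputError("all counts must be positive")
        if not (0.0 <= self.multi_parent_fraction <= 1.0):
            raise InputError("multi_parent_fraction must be in [0, 1]")
        if self.seed is None:
            raise InputError("seed is mandatory")


@dataclass
class SimData:
    """One simulated dataset: the DAG, its tree transform, hidden tree
    states, DAG states S*_j = max over GT_j, and tree-node p-values."""

    config: SimConfig
    dag: GoDag
    tree: GoTree
    mapping: DagTreeMap
    states: np.ndarray
    pvals: np.ndarray
    dag_states: dict[str, int] = field(default_factory=dict)


def random_dag(config: SimConfig) -> GoDag:
    """Grow a random rooted tree, add extra parent edges to a fraction of
    nodes (from non-descendants only, preserving acyclicity), assign genes
    to leaves, and propagate annotations upward via :func:`load_dag`."""
    rng = np.random.default_rng(config.seed)
    n = config.n_dag_nodes
    width = max(4, len(str(n)))
    names = [f"T{i:0{width}d}" for i in range(n)]

    parent = np.full(n, -1, dtype=np.int64)
    n_children = np.zeros(n, dtype=np.int64)
    open_nodes = [0]  # nodes that can still accept children
    for v in range(1, n):
        idx = int(rng.integers(len(open_nodes)))
        u = open_nodes[idx]
        parent[v] = u
        n_children[u] += 1
        if n_children[u] >= config.max_children:
            open_nodes.pop(idx)
        open_nodes.append(v)

    edges = [(names[parent[v]], names[v]) for v in range(1, n)]

    n_extra = int(round(config.multi_parent_fraction * (n - 1)))
    if n_extra:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(n))
        g.add_edges_from((int(parent[v]), v) for v in range(1, n))
        candidates = rng.permutation(np.arange(1, n))
        added = 0
        for v in candidates:
            v = int(v)
            if added >= n_extra:
                break
            # the extra parent must be neither an ancestor (edge would be
            # redundant) nor a descendant (edge would close a cycle) of v
            forbidden = nx.ancestors(g, v) | nx.descendants(g, v) | {v}
            pool = [u for u in range(n) if u not in forbidden]
            if not pool:
                continue
            u = int(pool[int(rng.integers(len(pool)))])
            edges.append((names[u], names[v]))
            g.add_edge(u, v)
            added += 1

    # genes on the leaves: each leaf gets one unique gene, the rest spread
    has_child = set(parent[1:].tolist()) | set()
    leaves = [v for v in range(n) if v not in has_child]
    if config.n_genes < len(leaves):
        raise InputError(
            f"need at least one gene per leaf: {len(leaves)} leaves, "
            f"{config.n_genes} genes"
        )
    gwidth = max(4, len(str(config.n_genes)))
    genes = [f"g{i:0{gwidth}d}" for i in range(config.n_genes)]
    annotations = [(genes[i], names[leaves[i]]) for i in range(len(leaves))]
    extra_assign = rng.integers(0, len(leaves), size=config.n_genes - len(leaves))
    for off, leaf_idx in enumerate(extra_assign):
        annotations.append((genes[len(leaves) + off], names[leaves[int(leaf_idx)]]))

    return load_dag(sorted(set(edges)), annotations)


def simulate_states(
    tree: GoTree, pi: float, omega: float, seed: int
) -> np.ndarray:
    """Sample hidden states: root ~ Bernoulli(π); a child of a state-1
    parent ~ Bernoulli(ω); a child of a state-0 parent is 0."""
    rng = np.random.default_rng(seed)
    n = tree.n_nodes
    u = rng.random(n)
    states = np.zeros(n, dtype=np.int8)
    states[0] = u[0] < pi
    for i in range(1, n):  # positions are depth-sorted: parent before child
        states[i] = states[tree.parent[i]] and (u[i] < omega)
    return states


def simulate_pvalues(states: np.ndarray, theta: HmtmParams, seed: int) -> np.ndarray:
    """Draw p-values conditionally independent given the states: beta(α, β)
    for state 1; the λ-uniform / (1−λ)-beta(α0, β0) mixture for state 0."""
    rng = np.random.default_rng(seed)
    n = len(states)
    alt = rng.beta(theta.alpha, theta.beta, size=n)
    unif = rng.random(n)
    null_beta = rng.beta(theta.alpha0, theta.beta0, size=n)
    pick_unif = rng.random(n) < theta.lam
    null = np.where(pick_unif, unif, null_beta)
    return clip_pvalues(np.where(np.asarray(states) == 1, alt, null))


def simulate_dataset(config: SimConfig) -> SimData:
    """End-to-end draw: DAG -> tree transform -> states -> p-values, with
    DAG-level truth S*_j = max of the comprising tree-node states."""
    dag = random_dag(config)
    tree, mapping = transform_to_tree(transitive_reduce(dag))
    # child seeds derived from the master seed, kept below 2**31
    sub = np.random.default_rng(config.seed).integers(0, 2**31 - 1, size=2)
    states = simulate_states(tree, config.theta.pi, config.theta.omega, int(sub[0]))
    pvals = simulate_pvalues(states, config.theta, int(sub[1]))
    dag_states = {
        j: int(max(states[k] for k in ks)) for j, ks in mapping.tree_nodes.items()
    }
    return SimData(
        config=config,
        dag=dag,
        tree=tree,
        mapping=mapping,
        states=states,
        pvals=pvals,
        dag_states=dag_states,
    )


# ---------------------------------------------------------------------------
# enumeration oracles


def _consistent_configs(tree: GoTree) -> list[tuple[int, ...]]:
    """All logically consistent state configurations (up-closed 1-sets)."""
    n = tree.n_nodes
    if n > _ENUM_CAP:
        raise InputError(f"enumeration capped at {_ENUM_CAP} nodes, got {n}")
    configs: list[tuple[int, ...]] = []
    states = [0] * n

    def rec(i: int) -> None:
        if i == n:
            configs.append(tuple(states))
            return
        if i > 0 and states[tree.parent[i]] == 0:
            states[i] = 0
            rec(i + 1)
        else:
            for s in (0, 1):
                states[i] = s
                rec(i + 1)
        states[i] = 0

    rec(0)
    return configs


def _config_weight(
    tree: GoTree, states: tuple[int, ...], e: np.ndarray, theta: HmtmParams
) -> float:
    q = theta.transition_matrix
    w = theta.pi if states[0] == 1 else 1.0 - theta.pi
    for i in range(1, tree.n_nodes):
        w *= q[states[tree.parent[i]], states[i]]
    for i in range(tree.n_nodes):
        w *= e[i, states[i]]
    return w


def brute_force_likelihood(
    tree: GoTree, pvals: np.ndarray, theta: HmtmParams
) -> float:
    """Exact log-likelihood by summing over consistent configurations."""
    e = emission_matrix(np.asarray(pvals, dtype=float), theta)
    total = sum(
        _config_weight(tree, s, e, theta) for s in _consistent_configs(tree)
    )
    return float(np.log(total))


def brute_force_posteriors(
    tree: GoTree,
    pvals: np.ndarray,
    theta: HmtmParams,
    targets: list[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float | None]:
    """Exact posteriors by enumeration: smoothed marginals P(S_i = 1 | p),
    pairwise expectations E[I(S_parent = 1, S_i = 1)] and
    E[I(S_parent = 1, S_i = 0)] (index 0 unused), and — if ``targets`` is
    given — P(any target in state 1 | p)."""
    n = tree.n_nodes
    e = emission_matrix(np.asarray(pvals, dtype=float), theta)
    total = 0.0
    marg = np.zeros(n)
    e11 = np.zeros(n)
    e10 = np.zeros(n)
    p_any = 0.0
    target_set = set(targets) if targets is not None else None
    for s in _consistent_configs(tree):
        w = _config_weight(tree, s, e, theta)
        total += w
        for i in range(n):
            if s[i] == 1:
                marg[i] += w
        for i in range(1, n):
            if s[tree.parent[i]] == 1:
                if s[i] == 1:
                    e11[i] += w
                else:
                    e10[i] += w
        if target_set is not None and any(s[t] == 1 for t in target_set):
            p_any += w
    marg /= total
    e11 /= total
    e10 /= total
    return marg, e11, e10, (p_any / total if target_set is not None else None)
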
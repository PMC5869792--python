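"""From tree beliefs to DAG-level posterior probabilities of differential
expression (PDEs), rejection sets, and an FDR estimate.

A DAG node j is DE exactly when any of its comprising tree nodes (the index
set GT_j) is in state 1.  Given all p-values, tree-node states are
conditionally independent given their parent's state, so the probability
that every target in GT_j is null factorizes over the minimal subtree
spanning the targets, with per-edge conditional transition probabilities
c_i = P(S_i = 1 | p, S_parent = 1).  The FDR of a rejection set R is
estimated as 1 − mean(PDE over R).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, NumericalError
from .go_graph import DagTreeMap, GoDag, GoTree
from .inference import Beliefs
from .model import HmtmParams

__all__ = [
    "PdeTable",
    "RejectionReport",
    "conditional_c",
    "pde_for_target_set",
    "pde_all_dag_nodes",
    "estimate_fdr",
    "reject_by_threshold",
]

_C_CLIP_TOL = 1e-8  # violations beyond this are bugs, not rounding


@dataclass
class PdeTable:
    """Per-tree-node conditional transition probabilities and per-DAG-node
    PDEs.  ``table`` has one row per DAG node: term_id, pde, n_genes,
    n_tree_nodes."""

    c: np.ndarray
    table: pd.DataFrame

    def write_tsv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class RejectionReport:
    threshold: float
    rejected: list[str]
    fdr_estimate: float | None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "threshold": self.threshold,
            "n_rejected": len(self.rejected),
            "rejected": self.rejected,
            "fdr_estimate": self.fdr_estimate,
            "note": (
                "FDR control is not guaranteed under gene-set overlap; "
                "consider an FWER-controlling screen as a first step"
            ),
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def conditional_c(tree: GoTree, beliefs: Beliefs, theta: HmtmParams) -> np.ndarray:
    """c_i = P(S_i = 1 | p, S_parent = 1) = ω·τ_i(1) / (τ_{ρ(i),i}(1)·P(S_i=1))
    for non-root nodes; for the root, c_1 = τ_1(1) = P(S_1 = 1 | p)."""
    n = tree.n_nodes
    c = np.zeros(n)
    c[0] = beliefs.tau[0, 1]
    if n > 1:
        i = np.arange(1, n)
        num = theta.omega * beliefs.tau[i, 1]
        den = beliefs.tau_edge[i, 1] * beliefs.prior[i, 1]
        bad = (den == 0.0) & (num != 0.0)
        if np.any(bad):
            node = tree.ids[int(i[bad][0])]
            raise NumericalError(f"denominator underflow computing c at {node!r}")
        out = np.zeros(n - 1)
        np.divide(num, den, out=out, where=den != 0.0)
        if np.any(out > 1.0 + _C_CLIP_TOL) or np.any(out < -_C_CLIP_TOL):
            worst = int(i[np.argmax(np.abs(out - 0.5))])
            raise NumericalError(
                f"conditional probability far outside [0, 1] at {tree.ids[worst]!r}"
            )
        c[i] = np.clip(out, 0.0, 1.0)
    return c


def pde_for_target_set(
    tree: GoTree, c: np.ndarray, targets: Iterable[int]
) -> float:
    """P(any target tree node is in state 1 | p) by a dynamic program on the
    minimal subtree spanning {root} ∪ targets.

    h(v) = P(all targets below-or-at v are 0 | parent of v is 1, p)
         = (1 − c_v) + c_v·[0 if v is a target else Π h(children of v with
           targets beneath)]; the answer is 1 − h(root)."""
    targets = set(int(t) for t in targets)
    if not targets:
        raise InputError("target set is empty")
    n = tree.n_nodes
    if any(t < 0 or t >= n for t in targets):
        raise InputError(f"target index outside [0, {n})")

    # minimal spanning subtree: all targets plus their ancestors up to root
    relevant: set[int] = set()
    for t in targets:
        v = t
        while v != -1 and v not in relevant:
            relevant.add(v)
            v = int(tree.parent[v])
    rel_children: dict[int, list[int]] = {v: [] for v in relevant}
    for v in relevant:
        if v != 0:
            rel_children[int(tree.parent[v])].append(v)

    h: dict[int, float] = {}
    for v in sorted(relevant, key=lambda x: -int(tree.depth[x])):
        if v in targets:
            inner = 0.0
        else:
            inner = 1.0
            for u in rel_children[v]:
                inner *= h[u]
        h[v] = (1.0 - c[v]) + c[v] * inner
    return 1.0 - h[0]


def pde_all_dag_nodes(
    dag: GoDag, mapping: DagTreeMap, tree: GoTree, c: np.ndarray
) -> PdeTable:
    """PDE_j for every DAG node, using its comprising tree-node set GT_j."""
    rows = []
    for term in dag.nodes:
        gt = mapping.tree_nodes.get(term)
        if not gt:
            raise InputError(f"no tree nodes recorded for DAG node {term!r}")
        rows.append(
            {
                "term_id": term,
                "pde": pde_for_target_set(tree, c, gt),
                "n_genes": len(dag.gene_sets[term]),
                "n_tree_nodes": len(gt),
            }
        )
    return PdeTable(c=c, table=pd.DataFrame(rows))


def pde_table_from_mapping(
    mapping: DagTreeMap, tree: GoTree, c: np.ndarray
) -> PdeTable:
    """Like :func:`pde_all_dag_nodes` but without the DAG object: gene
    counts come from the union of the comprising tree gene sets, which the
    transformation guarantees reconstructs each DAG node's gene set."""
    rows = []
    for term in sorted(mapping.tree_nodes):
        gt = mapping.tree_nodes[term]
        if not gt:
            raise InputError(f"no tree nodes recorded for DAG node {term!r}")
        union: set[str] = set()
        for k in gt:
            union |= tree.gene_sets[k]
        rows.append(
            {
                "term_id": term,
                "pde": pde_for_target_set(tree, c, gt),
                "n_genes": len(union),
                "n_tree_nodes": len(gt),
            }
        )
    return PdeTable(c=c, table=pd.DataFrame(rows))


def estimate_fdr(pde_values: Sequence[float]) -> float:
    """FDR estimate for a rejection set: 1 − mean PDE of its members."""
    values = np.asarray(list(pde_values), dtype=float)
    if values.size == 0:
        raise InputError("rejection set is empty; FDR estimate undefined")
    return float(1.0 - values.mean())


def reject_by_threshold(table: PdeTable, threshold: float = 0.99) -> RejectionReport:
    """Reject every DAG node with PDE ≥ threshold.  Because PDEs are
    monotone along DAG edges, the rejection set is ancestor-closed."""
    if not (0.0 < threshold < 1.0):
        raise InputError(f"threshold must be in (0, 1), got {threshold!r}")
    hits = table.table[table.table["pde"] >= threshold]
    rejected = sorted(hits["term_id"].tolist())
    fdr = estimate_fdr(hits["pde"].to_numpy()) if len(rejected) else None
    return RejectionReport(threshold=threshold, rejected=rejected, fdr_estimate=fdr)
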
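"""Ontology graph handling: loading, annotation propagation, transitive
reduction, and the DAG-to-tree transformation.

A GO-style ontology is a rooted DAG whose edges run from general terms to
more specific terms, so each edge implies a gene-set superset/subset
relationship.  Belief propagation requires a tree, so the DAG is transformed
into a spanning tree with nested, carved gene sets: every node with several
parents keeps exactly one incoming edge, and the genes of the severed child
are removed from the parents that lost the edge.  Each original DAG node is
then recoverable as the union of the tree nodes whose gene sets it contains
(its ``GT_j`` index set), which is what lets tree-level posteriors be mapped
back onto the DAG.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

from .errors import InputError, StructuralError

logger = logging.getLogger(__name__)

__all__ = [
    "GoDag",
    "GoTree",
    "DagTreeMap",
    "load_dag",
    "transitive_reduce",
    "transform_to_tree",
    "read_edge_tsv",
    "read_obo_edges",
    "read_annotation_tsv",
    "write_tree",
    "read_tree",
]


@dataclass
class GoDag:
    """A rooted DAG of terms with upward-propagated gene sets.

    ``graph`` stores parent->child edges (general -> specific).  After
    :func:`load_dag`, every node's gene set contains the union of its
    descendants' gene sets and empty terms have been dropped.
    """

    graph: nx.DiGraph
    gene_sets: dict[str, frozenset[str]]
    root: str

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)

    def validate(self) -> "GoDag":
        if not nx.is_directed_acyclic_graph(self.graph):
            raise StructuralError("term graph contains a cycle")
        roots = [n for n in self.graph.nodes if self.graph.in_degree(n) == 0]
        if len(roots) != 1:
            raise StructuralError(
                f"expected exactly one root, found {len(roots)}: {sorted(roots)[:5]}"
            )
        for u, v in self.graph.edges:
            if not self.gene_sets[v] <= self.gene_sets[u]:
                raise StructuralError(
                    f"gene set of {v!r} is not a subset of its parent {u!r}"
                )
        for n in self.graph.nodes:
            if not self.gene_sets[n]:
                raise StructuralError(f"node {n!r} has an empty gene set")
        return self


@dataclass
class GoTree:
    """Spanning tree over (surviving) DAG nodes with carved gene sets.

    Nodes are stored positionally: position 0 is the root and positions are
    sorted by (depth, identifier), so arrays indexed by position line up
    across the package.  ``T_i ⊆ T_parent(i)`` holds for every non-root node.
    """

    ids: list[str]
    parent: np.ndarray  # parent[0] == -1
    gene_sets: list[frozenset[str]]

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.index = {t: i for i, t in enumerate(self.ids)}
        n = len(self.ids)
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            self.children[self.parent[i]].append(i)
        self.depth = np.zeros(n, dtype=np.int64)
        for i in range(1, n):
            self.depth[i] = self.depth[self.parent[i]] + 1

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    def levels(self) -> list[np.ndarray]:
        """Node positions grouped by depth, shallowest first."""
        out = []
        for d in range(int(self.depth.max()) + 1):
            out.append(np.flatnonzero(self.depth == d))
        return out

    def validate(self) -> "GoTree":
        if self.parent[0] != -1:
            raise StructuralError("root must be at position 0 with parent -1")
        for i in range(1, self.n_nodes):
            if not (0 <= self.parent[i] < i):
                raise StructuralError(f"node {i} has invalid parent {self.parent[i]}")
            if not self.gene_sets[i] <= self.gene_sets[self.parent[i]]:
                raise StructuralError(f"gene set of tree node {i} not nested in parent")
        if any(not g for g in self.gene_sets):
            raise StructuralError("tree contains an empty gene set")
        return self


@dataclass
class DagTreeMap:
    """Mapping between DAG nodes and the tree nodes that compose them.

    ``tree_nodes[j]`` is the index set ``GT_j`` = {k : T_k ⊆ G_j} as tree
    positions; ``carved_from[k]`` names the DAG node tree node ``k`` was
    carved out of; ``dropped`` records DAG nodes whose carved gene set
    became empty, mapped to the surviving tree ancestor they collapsed into.
    """

    tree_nodes: dict[str, list[int]]
    carved_from: list[str]
    dropped: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# loading


def read_edge_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Read a `parent<TAB>child` edge list with a header row."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"edge file not found: {path}")
    edges = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise InputError(f"empty edge file: {path}")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise InputError(f"{path}:{ln}: expected 2 columns, got {len(parts)}")
            edges.append((parts[0], parts[1]))
    if not edges:
        raise InputError(f"no edges in {path}")
    return edges


def read_obo_edges(path: str | Path) -> list[tuple[str, str]]:
    """Extract general->specific edges from an OBO file, `is_a` only.

    OBO files record `is_a` from the specific term to the general term;
    edges are reversed here so they run parent -> child like the TSV dialect.
    """
    import obonet

    path = Path(path)
    if not path.exists():
        raise InputError(f"OBO file not found: {path}")
    graph = obonet.read_obo(path)
    edges = []
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            edges.append((parent, child))
    if not edges:
        raise InputError(f"no is_a edges found in {path}")
    return sorted(edges)


def read_annotation_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Read a `gene_id<TAB>term_id` annotation table with a header row."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    rows = []
    with open(path) as fh:
        fh.readline()
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise InputError(f"{path}:{ln}: expected 2 columns, got {len(parts)}")
            rows.append((parts[0], parts[1]))
    return rows


def load_dag(
    edges: Iterable[tuple[str, str]],
    annotations: Iterable[tuple[str, str]],
) -> GoDag:
    """Build a :class:`GoDag` from a parent->child edge list and gene/term
    annotation pairs.

    Annotations are propagated upward (a gene annotated to a term is
    annotated to every ancestor), terms left empty are dropped, and the
    structure is checked: acyclic with exactly one root.  Annotations that
    reference unknown terms are skipped with a warning.
    """
    edges = list(edges)
    if not edges:
        raise InputError("edge table is empty")
    g = nx.DiGraph()
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise StructuralError("term graph contains a cycle")
    roots = sorted(n for n in g.nodes if g.in_degree(n) == 0)
    if len(roots) != 1:
        raise StructuralError(
            f"expected exactly one root, found {len(roots)}: {roots[:5]}"
        )

    direct: dict[str, set[str]] = {n: set() for n in g.nodes}
    n_skipped = 0
    for gene, term in annotations:
        if term not in direct:
            n_skipped += 1
            logger.warning("annotation %s -> unknown term %s skipped", gene, term)
            continue
        direct[term].add(gene)
    if n_skipped:
        logger.warning("skipped %d annotations with unknown terms", n_skipped)

    # children before parents: reversed lexicographic topological order
    order = list(nx.lexicographical_topological_sort(g))
    gene_sets: dict[str, set[str]] = {}
    for n in reversed(order):
        acc = set(direct[n])
        for c in g.successors(n):
            acc |= gene_sets[c]
        gene_sets[n] = acc

    empty = [n for n in g.nodes if not gene_sets[n]]
    if roots[0] in empty:
        raise StructuralError("no gene is annotated to any term")
    if empty:
        logger.info("dropping %d empty terms", len(empty))
        g.remove_nodes_from(empty)

    dag = GoDag(
        graph=g,
        gene_sets={n: frozenset(gene_sets[n]) for n in g.nodes},
        root=roots[0],
    )
    return dag.validate()


# ---------------------------------------------------------------------------
# transformation


def transitive_reduce(dag: GoDag) -> GoDag:
    """Remove every edge u->v for which another directed u->...->v path
    exists; gene sets are untouched."""
    reduced = nx.transitive_reduction(dag.graph)
    return GoDag(graph=reduced, gene_sets=dict(dag.gene_sets), root=dag.root)


def transform_to_tree(dag: GoDag) -> tuple[GoTree, DagTreeMap]:
    """Transform a transitively reduced DAG into a spanning tree with carved,
    nested gene sets, and compute the DAG<->tree node map.

    For each multi-parent node the parent with the largest gene set is
    retained (ties broken by lexicographically smallest identifier); the
    retained edges form the spanning tree.  Severing an edge is equivalent
    to removing the child's genes from the parents that lost it, so the
    carved gene set of a tree node collects the annotations that originate
    at or below it *in the tree*: each gene's originating terms are the DAG
    nodes where it is not explained by any child (G_v minus the union of the
    children's gene sets), and these origin sets are propagated up the
    retained tree.  Because every tree descendant is also a DAG descendant,
    each tree node's gene set is a subset of every DAG node above its
    origin, which guarantees that every DAG node is exactly the union of
    the tree nodes comprising it.  Nodes whose carved set is empty (all
    their annotations travelled through severed edges) are dropped together
    with their — necessarily empty — tree subtrees.

    Raises :class:`StructuralError` if some DAG node cannot be reconstructed
    as the union of its comprising tree nodes.
    """
    g = dag.graph
    gs = dag.gene_sets
    order = list(nx.lexicographical_topological_sort(g))

    # step 1: retained parent per node (fixes the tree topology)
    tree_parent: dict[str, str | None] = {}
    tree_children: dict[str, list[str]] = {v: [] for v in order}
    for v in order:
        parents = sorted(g.predecessors(v))
        if not parents:
            tree_parent[v] = None
        else:
            best = min(parents, key=lambda u: (-len(gs[u]), u))
            tree_parent[v] = best
            tree_children[best].append(v)

    # step 2: genes originate where no child explains them, and propagate
    # up the retained tree (children before parents)
    carved: dict[str, frozenset[str]] = {}
    for v in reversed(order):
        acc = set(gs[v])
        for c in g.successors(v):
            acc -= gs[c]
        for c in tree_children[v]:
            acc |= carved[c]
        carved[v] = frozenset(acc)

    # step 3: drop empty subtrees, recording the nearest surviving ancestor
    dropped: dict[str, str] = {}
    for v in order[1:]:
        if not carved[v]:
            p = tree_parent[v]
            assert p is not None
            dropped[v] = dropped.get(p, p)
            logger.info("tree node %s carved empty; subtree dropped", v)

    # step 4: positional re-indexing, root first, then by (depth, id)
    depth: dict[str, int] = {dag.root: 0}
    for v in order[1:]:
        if v not in dropped:
            p = tree_parent[v]
            assert p is not None and p not in dropped
            depth[v] = depth[p] + 1
    surviving = sorted(depth, key=lambda n: (depth[n], n))
    eff_parent = {v: tree_parent[v] for v in surviving if v != dag.root}
    pos = {n: i for i, n in enumerate(surviving)}
    parent = np.array(
        [-1] + [pos[eff_parent[n]] for n in surviving[1:]], dtype=np.int64
    )
    tree = GoTree(
        ids=surviving,
        parent=parent,
        gene_sets=[carved[n] for n in surviving],
    ).validate()

    # step 4: GT_j = {k : T_k ⊆ G_j} via per-gene term-membership intersection
    terms_with_gene: dict[str, set[str]] = {}
    for j, genes in gs.items():
        for gene in genes:
            terms_with_gene.setdefault(gene, set()).add(j)
    gt: dict[str, list[int]] = {j: [] for j in g.nodes}
    for k, t_k in enumerate(tree.gene_sets):
        it = iter(t_k)
        members = set(terms_with_gene[next(it)])
        for gene in it:
            members &= terms_with_gene[gene]
            if not members:
                break
        for j in members:
            gt[j].append(k)
    for j in gt:
        gt[j].sort()

    # reconstruction guarantee: every DAG node is the union of its tree nodes
    for j in g.nodes:
        union: set[str] = set()
        for k in gt[j]:
            union |= tree.gene_sets[k]
        if union != gs[j]:
            missing = sorted(gs[j] - union)[:10]
            raise StructuralError(
                f"DAG node {j!r} cannot be reconstructed from its tree nodes; "
                f"uncovered genes include {missing}"
            )

    mapping = DagTreeMap(tree_nodes=gt, carved_from=list(surviving), dropped=dropped)
    return tree, mapping


# ---------------------------------------------------------------------------
# serialization


def write_tree(tree: GoTree, mapping: DagTreeMap, prefix: str | Path) -> None:
    """Write `<prefix>.tree.tsv` and `<prefix>.map.json`."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.tree.tsv", "w") as fh:
        fh.write("node_id\tparent_id\tn_genes\tgene_list\n")
        for i, node in enumerate(tree.ids):
            parent_id = "" if i == 0 else tree.ids[tree.parent[i]]
            genes = ",".join(sorted(tree.gene_sets[i]))
            fh.write(f"{node}\t{parent_id}\t{len(tree.gene_sets[i])}\t{genes}\n")
    payload = {
        "tree_nodes": mapping.tree_nodes,
        "carved_from": mapping.carved_from,
        "dropped": mapping.dropped,
    }
    with open(f"{prefix}.map.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_tree(prefix: str | Path) -> tuple[GoTree, DagTreeMap]:
    """Read a tree/map pair written by :func:`write_tree`."""
    tree_path = Path(f"{prefix}.tree.tsv")
    map_path = Path(f"{prefix}.map.json")
    for p in (tree_path, map_path):
        if not p.exists():
            raise InputError(f"file not found: {p}")
    ids: list[str] = []
    parents: list[str] = []
    gene_sets: list[frozenset[str]] = []
    with open(tree_path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            node, parent_id, _, genes = line.rstrip("\n").split("\t")
            ids.append(node)
            parents.append(parent_id)
            gene_sets.append(frozenset(genes.split(",")) if genes else frozenset())
    index = {t: i for i, t in enumerate(ids)}
    parent = np.array(
        [-1 if p == "" else index[p] for p in parents], dtype=np.int64
    )
    tree = GoTree(ids=ids, parent=parent, gene_sets=gene_sets).validate()
    with open(map_path) as fh:
        payload = json.load(fh)
    mapping = DagTreeMap(
        tree_nodes={j: list(v) for j, v in payload["tree_nodes"].items()},
        carved_from=list(payload["carved_from"]),
        dropped=dict(payload["dropped"]),
    )
    return tree, mapping
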
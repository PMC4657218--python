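"""Per-tree quantities underlying the locus statistics.

All functions operate on :class:`dendropy.Tree` objects (as returned by
:func:`phylosieve.io_formats.read_trees`) and use *unrooted* edge
semantics: when a tree is stored in rooted-binary form (root of degree
two), the two root-adjacent edges are merged into one, so edge counts
and pendant lengths match the unrooted tree that a maximum-likelihood
program actually inferred.  Path lengths are unaffected by rooting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import dendropy
import numpy as np

__all__ = [
    "DistanceMatrix",
    "EdgeStats",
    "patristic_matrix",
    "edge_stats",
    "average_support",
    "flag_spurious",
]


@dataclass
class DistanceMatrix:
    """A symmetric taxon-by-taxon distance matrix with zero diagonal.

    ``values[i, j]`` is the distance between ``labels[i]`` and
    ``labels[j]``; ``nan`` marks an undefined entry (e.g. a sequence
    pair with no comparable sites).
    """

    labels: Tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"distance matrix shape {self.values.shape} does not match "
                f"{n} labels"
            )
        if not np.allclose(
            self.values, self.values.T, equal_nan=True, rtol=0, atol=1e-12
        ):
            raise ValueError("distance matrix is not symmetric")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class EdgeStats:
    """Edge-length summary of one tree (unrooted edge semantics)."""

    total_length: float
    n_edges: int
    mean_edge_length: float
    terminal_lengths: Dict[str, float]


def _edge_name(node: dendropy.Node) -> str:
    if node.is_leaf():
        return f"terminal edge of {node.taxon.label!r}"
    leaves = [leaf.taxon.label for leaf in node.leaf_iter()]
    return f"internal edge above {{{', '.join(sorted(leaves)[:3])}...}}"


def _unrooted_edges(tree: dendropy.Tree) -> List[Tuple[Optional[dendropy.Node], float]]:
    """Edge list as ``(leaf node or None, length)`` with root-degree-2 merging.

    The leaf node is set for terminal edges (the merged root edge is
    terminal when one of the root's children is a leaf).  Raises
    ``ValueError`` when a required edge length is missing.
    """
    root = tree.seed_node
    children = root.child_nodes()
    edges: List[Tuple[Optional[dendropy.Node], float]] = []

    def _length(node: dendropy.Node) -> float:
        if node.edge.length is None:
            raise ValueError(f"missing edge length on {_edge_name(node)}")
        return float(node.edge.length)

    merged_children = set()
    if len(children) == 2:
        # Rooted-binary representation of an unrooted tree: the root
        # subdivides one real edge; undo the subdivision.
        merged = _length(children[0]) + _length(children[1])
        leafish = [c for c in children if c.is_leaf()]
        edges.append((leafish[0] if len(leafish) == 1 else None, merged))
        if len(leafish) == 2:
            # Two-leaf tree: the single edge is terminal for both taxa;
            # represent it once, attributed to the first leaf.
            edges[-1] = (leafish[0], merged)
        merged_children = set(children)

    for node in tree.preorder_node_iter():
        if node is root or node in merged_children:
            continue
        edges.append((node if node.is_leaf() else None, _length(node)))
    return edges


def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Pairwise path-length (patristic) distances between all leaves.

    Entry (i, j) is the sum of edge lengths on the unique i-j path;
    the result is independent of root placement.
    """
    leaves = list(tree.leaf_node_iter())
    # validate edge lengths up front for a clear error message
    _unrooted_edges(tree)
    labels = tuple(leaf.taxon.label for leaf in leaves)
    pdm = tree.phylogenetic_distance_matrix()
    n = len(leaves)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values)


def edge_stats(tree: dendropy.Tree) -> EdgeStats:
    """Total tree length, edge count, mean edge length and pendant lengths.

    The mean edge length (total tree length divided by the number of
    internal plus terminal edges) is the rate-of-evolution proxy used
    for locus ranking.
    """
    edges = _unrooted_edges(tree)
    if not edges:
        raise ValueError("no edges: tree has a single leaf")
    total = float(sum(length for _, length in edges))
    n_edges = len(edges)
    terminal_lengths: Dict[str, float] = {}
    for leaf_node, length in edges:
        if leaf_node is not None:
            terminal_lengths[leaf_node.taxon.label] = length
    # a two-leaf tree has one edge that is pendant for both taxa
    root_children = tree.seed_node.child_nodes()
    if len(root_children) == 2 and all(c.is_leaf() for c in root_children):
        shared = edges[0][1]
        for child in root_children:
            terminal_lengths[child.taxon.label] = shared
    return EdgeStats(
        total_length=total,
        n_edges=n_edges,
        mean_edge_length=total / n_edges,
        terminal_lengths=terminal_lengths,
    )


def average_support(tree: dendropy.Tree) -> Optional[float]:
    """Arithmetic mean of internal-node support values, or None if absent.

    Uses the percent-scale ``node.support`` annotations set by
    :func:`phylosieve.io_formats.read_trees`; for trees built elsewhere,
    numeric internal-node labels are used directly (values all <= 1 are
    read as proportions).
    """
    values = []
    annotated = False
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        support = getattr(node, "support", None)
        if support is not None:
            values.append(float(support))
            annotated = True
        elif node.label is not None:
            try:
                values.append(float(node.label))
            except ValueError:
                continue
    if not values:
        return None
    if not annotated and max(values) <= 1.0:
        values = [v * 100.0 for v in values]
    return float(np.mean(values))


def flag_spurious(tree: dendropy.Tree, factor: float = 5.0) -> set:
    """Taxa whose pendant edge exceeds ``factor`` times the mean edge length.

    This is the spurious-sequence screen applied to single-gene trees:
    a terminal branch more than ``factor`` (default 5) times longer than
    the tree's average branch length marks a suspect sequence.  The
    average is taken over all edges including the candidate itself, in a
    single pass, and the comparison is strict (``>``).
    """
    if factor <= 0:
        raise ValueError(f"factor must be positive, got {factor}")
    stats = edge_stats(tree)
    threshold = factor * stats.mean_edge_length
    return {
        taxon
        for taxon, length in stats.terminal_lengths.items()
        if length > threshold
    }
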
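"""Circular layout via hierarchical-clustering leaf ordering.

Genes are placed on a circle so that most edges stay local to tight arcs.
The order comes from a sorting tree: build the time-union co-incidence
network (an edge counts if it passes the weight threshold at *any*
timepoint), measure pairwise gene similarity from neighbor-set overlap, and
agglomerate with average linkage.

The similarity blends two Jaccard coefficients over the union network:
``s = (2·J1 + J2) / 3``, where J1 compares closed one-step neighbor sets
(each gene's set includes itself, so directly connected genes look similar)
and J2 compares radius-2 neighborhoods. J1 is the primary signal — it is
what keeps chord endpoints adjacent on the circle — but in a sparse module
two genes can share no direct neighbor, leaving J1 = 0 exactly as for an
unrelated pair; the two-step term resolves those ties, because a connected
module of moderate density almost surely links any two members within a few
hops while genes of different modules stay disjoint at radius 2 when cross
edges are rare. Dissimilarity is 1 − s. One ordering is
computed from the union network and reused for every timepoint, keeping
node positions fixed while the edges rewire.

Leaf order is made deterministic by a tie-break at every merge: the subtree
whose lexicographically smallest leaf is smaller goes on the left. Genes
that are isolated in the union network (Jaccard is undefined against an
empty neighborhood) are appended after the clustered genes in lexicographic
order, joined to the tree at the root height.

Angle convention: position 0 sits at 12 o'clock and angles increase
clockwise, with equal spacing 2π/n.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .errors import UsageError, ValidationError
from .io import NetworkSeries, NetworkSnapshot

__all__ = [
    "TreeNode",
    "ClusterTree",
    "CircularLayout",
    "cluster_order",
    "locality_score",
    "assign_layout",
]


@dataclass(frozen=True)
class TreeNode:
    """Node of the sorting tree; leaves carry a gene label and height 0."""

    height: float
    children: tuple["TreeNode", ...] = ()
    label: str | None = None
    merge_index: int = -1  # creation order of internal nodes; -1 for leaves

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def min_leaf(self) -> str:
        return min(self.leaves())


@dataclass(frozen=True)
class ClusterTree:
    """Binary sorting tree whose left-to-right leaf sequence is the circle order."""

    root: TreeNode

    @property
    def leaf_order(self) -> tuple[str, ...]:
        return tuple(self.root.leaves())

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_order)


@dataclass(frozen=True)
class CircularLayout:
    """Angular positions, sizes and cluster colors for genes on a circle.

    ``angles`` are radians clockwise from 12 o'clock; ``colors`` are discrete
    cluster indices from cutting the sorting tree; ``order`` is the leaf order.
    """

    order: tuple[str, ...]
    angles: dict[str, float]
    radius: float
    node_size: dict[str, float]
    color: dict[str, int]


def _union_graph(series: NetworkSeries, min_weight: float) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(series.node_universe)
    for snap in series:
        for u, v, w in snap.edges:
            if w >= min_weight:
                g.add_edge(u, v)
    return g


def _ordered(children: Sequence[TreeNode]) -> tuple[TreeNode, ...]:
    return tuple(sorted(children, key=lambda c: c.min_leaf()))


def _jaccard_matrix(reach: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard similarity of the rows of a boolean reach matrix."""
    r = reach.astype(np.float64)
    inter = r @ r.T
    sizes = r.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    return inter / union  # union >= 1: every row contains the gene itself


def _dissimilarity(union_graph: nx.Graph, connected: Sequence[str]) -> np.ndarray:
    """1 − (2·J1 + J2)/3 over closed 1-step and radius-2 neighborhoods."""
    m = len(connected)
    idx = {n: i for i, n in enumerate(connected)}
    a1 = np.eye(m, dtype=bool)
    for u, v in union_graph.edges():
        if u in idx and v in idx:
            a1[idx[u], idx[v]] = a1[idx[v], idx[u]] = True
    a2 = (a1.astype(np.int64) @ a1.astype(np.int64)) > 0
    sim = (2.0 * _jaccard_matrix(a1) + _jaccard_matrix(a2)) / 3.0
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    return dist


def cluster_order(series: NetworkSeries, min_weight: float = 0.0) -> ClusterTree:
    """Build the sorting tree over the node universe from the time-union network."""
    if not series.node_universe:
        raise UsageError("cannot order an empty node universe")
    union = _union_graph(series, min_weight)
    connected = sorted(n for n in union if union.degree(n) > 0)
    isolated = sorted(n for n in union if union.degree(n) == 0)

    node: TreeNode | None = None
    merge_counter = itertools.count()
    if len(connected) == 1:  # cannot happen (edges need 2 endpoints) but harmless
        node = TreeNode(0.0, label=connected[0])
    elif connected:
        z = linkage(
            squareform(_dissimilarity(union, connected), checks=False),
            method="average",
        )
        nodes: list[TreeNode] = [TreeNode(0.0, label=n) for n in connected]
        for left_i, right_i, height, _count in z:
            children = _ordered((nodes[int(left_i)], nodes[int(right_i)]))
            nodes.append(
                TreeNode(float(height), children, merge_index=next(merge_counter))
            )
        node = nodes[-1]

    # Append isolated genes at/above the root height so heights stay monotone.
    if node is None:
        if len(isolated) == 1:
            return ClusterTree(TreeNode(0.0, label=isolated[0]))
        h = 1.0
        node = TreeNode(0.0, label=isolated[0])
        for lab in isolated[1:]:
            node = TreeNode(
                h, (node, TreeNode(0.0, label=lab)), merge_index=next(merge_counter)
            )
        return ClusterTree(node)
    h = max(node.height, 1.0)
    for lab in isolated:
        node = TreeNode(
            h, (node, TreeNode(0.0, label=lab)), merge_index=next(merge_counter)
        )
    return ClusterTree(node)


def locality_score(snapshot: NetworkSnapshot, order: Sequence[str]) -> int:
    """Sum over edges of the circular slot distance between endpoints.

    With n slots, positions i and j are min(|i−j|, n−|i−j|) apart; lower
    totals mean more edges stay local to short arcs.
    """
    order = list(order)
    if sorted(order) != sorted(snapshot.nodes) or len(set(order)) != len(order):
        raise ValidationError("order is not a permutation of the snapshot nodes")
    pos = {g: i for i, g in enumerate(order)}
    n = len(order)
    score = 0
    for u, v, _w in snapshot.edges:
        d = abs(pos[u] - pos[v])
        score += min(d, n - d)
    return score


def _cut_tree(root: TreeNode, k: int) -> list[TreeNode]:
    """Split the tree into k subtrees by removing the k−1 highest merges.

    Repeatedly replace the forest root with the largest height (ties: earlier
    merge first) by its children.
    """
    forest = [root]
    while len(forest) < k:
        internal = [t for t in forest if not t.is_leaf]
        pick = max(internal, key=lambda t: (t.height, -t.merge_index))
        forest.remove(pick)
        forest.extend(pick.children)
    return forest


def assign_layout(
    tree: ClusterTree,
    k_colors: int,
    size_by_degree: bool = False,
    snapshot: NetworkSnapshot | None = None,
    radius: float = 250.0,
    node_size_range: tuple[float, float] = (4.0, 16.0),
) -> CircularLayout:
    """Place leaves on the circle and color them by a k-cluster cut of the tree.

    Sizes are constant (midpoint of ``node_size_range``) unless
    ``size_by_degree``, in which case they are affine in the snapshot degree
    scaled to the range.
    """
    order = tree.leaf_order
    n = len(order)
    if k_colors < 1:
        raise ValidationError(f"k_colors must be >= 1, got {k_colors}")
    if k_colors > n:
        raise ValidationError(f"k_colors={k_colors} exceeds the {n} leaves")
    angles = {g: i * 2.0 * math.pi / n for i, g in enumerate(order)}

    clusters = _cut_tree(tree.root, k_colors)
    pos = {g: i for i, g in enumerate(order)}
    clusters.sort(key=lambda t: min(pos[g] for g in t.leaves()))
    color = {g: ci for ci, t in enumerate(clusters) for g in t.leaves()}

    smin, smax = node_size_range
    if smin > smax or smin <= 0:
        raise ValidationError(f"bad node_size_range {node_size_range}")
    if size_by_degree:
        if snapshot is None:
            raise UsageError("size_by_degree requires a snapshot")
        deg = {g: snapshot.graph.degree(g) if g in snapshot.graph else 0 for g in order}
        lo, hi = min(deg.values()), max(deg.values())
        if hi == lo:
            node_size = {g: smax for g in order}
        else:
            node_size = {
                g: smin + (smax - smin) * (deg[g] - lo) / (hi - lo) for g in order
            }
    else:
        node_size = {g: (smin + smax) / 2.0 for g in order}
    return CircularLayout(
        order=order, angles=angles, radius=radius, node_size=node_size, color=color
    )


def layout_to_tsv(layout: CircularLayout, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene\tangle_radians\tcolor_index\tsize\n")
        for g in layout.order:
            fh.write(
                f"{g}\t{layout.angles[g]:.6f}\t{layout.color[g]}\t{layout.node_size[g]:.3f}\n"
            )
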
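"""Per-timepoint and across-time network statistics.

Degree here is always an unweighted edge count after weight thresholding:
the stack view's band heights are integer degrees per timepoint, not weight
sums. Thresholding keeps edges with ``weight >= min_weight`` (an edge
strictly *below* the minimum disappears).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import GeneLookupError, UsageError, ValidationError
from .io import AnnotationMap, NetworkSeries, NetworkSnapshot

__all__ = [
    "DegreeMatrix",
    "EdgeLifetime",
    "EdgeClassification",
    "filter_edges",
    "degree_matrix",
    "group_degree_matrix",
    "edge_lifetimes",
    "activity_profile",
    "classify_incident_edges",
    "isolate_node",
]


@dataclass(frozen=True)
class DegreeMatrix:
    """Entities × timepoints table of integer degrees.

    ``frame`` is indexed by entity label (gene or group) with one column per
    time label, in series order.
    """

    frame: pd.DataFrame

    @property
    def entity_labels(self) -> list[str]:
        return list(self.frame.index)

    @property
    def time_labels(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self):
        return self.frame.to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="entity")

    def select(self, labels: Iterable[str]) -> "DegreeMatrix":
        keep = [e for e in self.entity_labels if e in set(labels)]
        return DegreeMatrix(self.frame.loc[keep])


@dataclass(frozen=True)
class EdgeLifetime:
    """Maximal runs of consecutive snapshot indices where an edge is active.

    ``intervals`` are inclusive 0-based ``(start, end)`` index pairs, disjoint,
    sorted, and maximal (adjacent runs are merged). For undirected series the
    edge key ``(source, target)`` is in sorted order.
    """

    source: str
    target: str
    intervals: tuple[tuple[int, int], ...]

    def intervals_as_labels(self, series: NetworkSeries) -> list[tuple[str, str]]:
        labels = series.time_labels
        return [(labels[a], labels[b]) for a, b in self.intervals]

    @property
    def total_active(self) -> int:
        return sum(b - a + 1 for a, b in self.intervals)


@dataclass(frozen=True)
class EdgeClassification:
    """Partition of a node's neighbors by edge direction.

    A neighbor is *bidirectional* when edges run both ways, *in_only* when
    only an edge into the node exists, *out_only* when only an edge out of
    the node exists. The three sets are pairwise disjoint and cover the
    neighbor set.
    """

    node: str
    in_only: frozenset[str]
    out_only: frozenset[str]
    bidirectional: frozenset[str]

    @property
    def neighbors(self) -> frozenset[str]:
        return self.in_only | self.out_only | self.bidirectional


def filter_edges(snapshot: NetworkSnapshot, min_weight: float) -> NetworkSnapshot:
    """Snapshot with the same nodes and only edges of weight >= ``min_weight``."""
    if min_weight < 0:
        raise ValidationError(f"min_weight must be >= 0, got {min_weight}")
    kept = [(u, v, d["weight"]) for u, v, d in snapshot.graph.edges(data=True)
            if d["weight"] >= min_weight]
    return NetworkSnapshot.from_edges(
        snapshot.time_label, snapshot.directed, kept, nodes=snapshot.nodes
    )


def degree_matrix(
    series: NetworkSeries, mode: str = "total", min_weight: float = 0.0
) -> DegreeMatrix:
    """Per-gene degree at each timepoint after thresholding.

    ``mode``: ``"out"`` counts edges leaving the gene, ``"in"`` edges entering,
    ``"total"`` all incident edges (a bidirectionally stored pair counts once
    per direction). Undirected series support only ``"total"``. Rows cover the
    full node universe in sorted order, so degree-0 genes keep their row.
    """
    if mode not in {"in", "out", "total"}:
        raise UsageError(f"mode must be one of in/out/total, got {mode!r}")
    if not series.directed and mode != "total":
        raise UsageError(f"mode {mode!r} is undefined for an undirected series")
    genes = sorted(series.node_universe)
    data = {}
    for snap in series:
        f = filter_edges(snap, min_weight)
        if series.directed:
            if mode == "out":
                deg = dict(f.graph.out_degree())
            elif mode == "in":
                deg = dict(f.graph.in_degree())
            else:
                deg = dict(f.graph.degree())  # in + out
        else:
            deg = dict(f.graph.degree())
        data[snap.time_label] = [deg.get(g, 0) for g in genes]
    frame = pd.DataFrame(data, index=genes, dtype=int)
    return DegreeMatrix(frame)


def group_degree_matrix(dm: DegreeMatrix, annotations: AnnotationMap) -> DegreeMatrix:
    """Sum gene rows into group rows.

    A gene carrying several group labels contributes its full degree to each
    of them, so with multi-membership annotation the group totals exceed the
    gene totals by design. Unannotated genes land in the ``"unannotated"`` row.
    """
    groups: dict[str, pd.Series] = {}
    for gene in dm.entity_labels:
        row = dm.frame.loc[gene]
        for group in annotations.groups(gene):
            if group in groups:
                groups[group] = groups[group] + row
            else:
                groups[group] = row.copy()
    if not groups:
        return DegreeMatrix(pd.DataFrame(columns=dm.time_labels, dtype=int))
    frame = pd.DataFrame({g: groups[g] for g in sorted(groups)}).T
    frame.columns = dm.time_labels
    return DegreeMatrix(frame.astype(int))


def _edge_key(u: str, v: str, directed: bool) -> tuple[str, str]:
    return (u, v) if directed else tuple(sorted((u, v)))  # type: ignore[return-value]


def edge_lifetimes(series: NetworkSeries, min_weight: float = 0.0) -> list[EdgeLifetime]:
    """One :class:`EdgeLifetime` per edge key ever active at >= ``min_weight``,
    sorted by edge key. Interval indices are 0-based snapshot positions."""
    if len(series) == 0:
        raise UsageError("edge_lifetimes requires a non-empty series")
    presence: dict[tuple[str, str], list[int]] = {}
    for t, snap in enumerate(series):
        for u, v, w in snap.edges:
            if w >= min_weight:
                presence.setdefault(_edge_key(u, v, series.directed), []).append(t)
    out = []
    for key in sorted(presence):
        times = sorted(presence[key])
        intervals: list[tuple[int, int]] = []
        start = prev = times[0]
        for t in times[1:]:
            if t == prev + 1:
                prev = t
            else:
                intervals.append((start, prev))
                start = prev = t
        intervals.append((start, prev))
        out.append(EdgeLifetime(key[0], key[1], tuple(intervals)))
    return out


def lifetimes_to_tsv(
    lifetimes: Sequence[EdgeLifetime], series: NetworkSeries, path: str | Path
) -> None:
    """Export lifetimes with user-facing time labels, one row per interval."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tinterval_start_label\tinterval_end_label\n")
        for lt in lifetimes:
            for a, b in lt.intervals_as_labels(series):
                fh.write(f"{lt.source}\t{lt.target}\t{a}\t{b}\n")


def activity_profile(
    series: NetworkSeries, min_weight: float = 0.0
) -> list[tuple[str, int]]:
    """Number of edges passing the threshold at each timepoint, in time order."""
    return [
        (snap.time_label, sum(1 for *_uv, w in snap.edges if w >= min_weight))
        for snap in series
    ]


def classify_incident_edges(snapshot: NetworkSnapshot, node: str) -> EdgeClassification:
    """Partition a node's neighbors into in-only / out-only / bidirectional."""
    if not snapshot.directed:
        raise UsageError("edge classification requires a directed snapshot")
    if node not in snapshot.graph:
        raise GeneLookupError(node)
    g = snapshot.graph
    succ = set(g.successors(node))
    pred = set(g.predecessors(node))
    return EdgeClassification(
        node=node,
        in_only=frozenset(pred - succ),
        out_only=frozenset(succ - pred),
        bidirectional=frozenset(succ & pred),
    )


def isolate_node(snapshot: NetworkSnapshot, node: str) -> NetworkSnapshot:
    """Induced subnetwork on the node and its neighbors, keeping only the
    edges incident to the node (neighbor-neighbor edges are dropped)."""
    if node not in snapshot.graph:
        raise GeneLookupError(node)
    g = snapshot.graph
    if snapshot.directed:
        neighbors = set(g.successors(node)) | set(g.predecessors(node))
        kept = [(u, v, d["weight"]) for u, v, d in g.edges(data=True)
                if u == node or v == node]
    else:
        neighbors = set(g.neighbors(node))
        kept = [(u, v, d["weight"]) for u, v, d in g.edges(data=True)
                if u == node or v == node]
    return NetworkSnapshot.from_edges(
        snapshot.time_label, snapshot.directed, kept, nodes={node} | neighbors
    )
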
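"""Reading and writing network series, annotation tables, and sorting trees.

Canonical file dialects
-----------------------
*Network series*: long-format, tab-separated, UTF-8, with the exact header
``time<TAB>source<TAB>target<TAB>weight``. One row per edge per timepoint.
Weights are positive decimals with a ``.`` separator. Directedness is a
property of the whole file, chosen by the caller, not encoded per row.

*Annotations*: two-column TSV ``gene<TAB>group``; a gene may appear on
several rows (one per group). Genes absent from the table belong to the
reserved group ``"unannotated"``.

*Sorting tree*: Newick, with gene identifiers as leaf labels and height
differences as branch lengths; the left-to-right leaf order of the string
equals the tree's leaf order.

Time labels are opaque strings. When every label parses as a number the
series is ordered numerically (so ``"2"`` precedes ``"10"``), otherwise
lexicographically — both microarray timepoints (``1..24``) and condition
labels (``S1``, ``T4``, ``T4R``) work as the series axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .errors import FormatError, ValidationError

SERIES_HEADER = ("time", "source", "target", "weight")
ANNOTATION_HEADER = ("gene", "group")
UNANNOTATED = "unannotated"

__all__ = [
    "NetworkSnapshot",
    "NetworkSeries",
    "AnnotationMap",
    "UNANNOTATED",
    "read_network_series",
    "write_network_series",
    "read_annotations",
    "write_annotations",
    "write_tree_newick",
    "newick_string",
    "write_snapshot_graphml",
    "sort_time_labels",
]


def sort_time_labels(labels: Iterable[str]) -> list[str]:
    """Natural ordering of time labels: numeric if all-numeric, else lexicographic."""
    labels = list(labels)
    try:
        return sorted(labels, key=float)
    except ValueError:
        return sorted(labels)


@dataclass(frozen=True)
class NetworkSnapshot:
    """One weighted network in a series, backed by a networkx graph.

    ``graph`` is an :class:`nx.DiGraph` when ``directed`` else :class:`nx.Graph`;
    edge weights live in the ``"weight"`` attribute. Nodes may exceed the edge
    endpoints (degree-0 genes are kept so layouts stay stable over time).
    """

    time_label: str
    directed: bool
    graph: nx.Graph = field(compare=False)

    @classmethod
    def from_edges(
        cls,
        time_label: str,
        directed: bool,
        edges: Iterable[tuple[str, str, float]],
        nodes: Iterable[str] = (),
    ) -> "NetworkSnapshot":
        g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
        g.add_nodes_from(nodes)
        for u, v, w in edges:
            if u == v:
                raise ValidationError(f"self-loop on {u!r} at time {time_label!r}")
            if not w > 0:
                raise ValidationError(
                    f"non-positive weight {w!r} on edge {u!r}-{v!r} at time {time_label!r}"
                )
            if g.has_edge(u, v):
                raise ValidationError(
                    f"duplicate edge {u!r}-{v!r} at time {time_label!r}"
                )
            g.add_edge(u, v, weight=float(w))
        return cls(time_label=time_label, directed=directed, graph=g)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def edges(self) -> frozenset[tuple[str, str, float]]:
        """Edge triples; for undirected snapshots endpoints are in sorted order."""
        if self.directed:
            return frozenset((u, v, d["weight"]) for u, v, d in self.graph.edges(data=True))
        return frozenset(
            (*sorted((u, v)), d["weight"]) for u, v, d in self.graph.edges(data=True)
        )

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["weight"]

    def with_nodes(self, nodes: Iterable[str]) -> "NetworkSnapshot":
        """Copy with extra (degree-0) nodes added."""
        g = self.graph.copy()
        g.add_nodes_from(nodes)
        return NetworkSnapshot(self.time_label, self.directed, g)


@dataclass(frozen=True)
class NetworkSeries:
    """Ordered sequence of snapshots sharing one node universe and directedness."""

    snapshots: tuple[NetworkSnapshot, ...]
    node_universe: frozenset[str]
    directed: bool

    def __post_init__(self) -> None:
        labels = [s.time_label for s in self.snapshots]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate time labels in series")
        if labels != sort_time_labels(labels):
            raise ValidationError("snapshots are not in ascending time order")
        for s in self.snapshots:
            if s.directed != self.directed:
                raise ValidationError("mixed directedness in series")
            if not s.nodes <= self.node_universe:
                raise ValidationError(
                    f"snapshot {s.time_label!r} has nodes outside the universe"
                )

    @classmethod
    def from_snapshots(
        cls, snapshots: Iterable[NetworkSnapshot], directed: bool
    ) -> "NetworkSeries":
        """Sort snapshots by natural time order and pad each to the full universe."""
        snaps = list(snapshots)
        universe: set[str] = set()
        for s in snaps:
            universe |= s.nodes
        order = {t: i for i, t in enumerate(sort_time_labels(s.time_label for s in snaps))}
        snaps.sort(key=lambda s: order[s.time_label])
        padded = tuple(s.with_nodes(universe) for s in snaps)
        return cls(padded, frozenset(universe), directed)

    @property
    def time_labels(self) -> tuple[str, ...]:
        return tuple(s.time_label for s in self.snapshots)

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)

    def __getitem__(self, i: int) -> NetworkSnapshot:
        return self.snapshots[i]

    def snapshot(self, time_label: str) -> NetworkSnapshot:
        for s in self.snapshots:
            if s.time_label == time_label:
                return s
        raise KeyError(time_label)


class AnnotationMap:
    """Gene → set-of-group-labels mapping with an ``"unannotated"`` fallback."""

    def __init__(self, entries: Mapping[str, Iterable[str]] | None = None) -> None:
        self._entries: dict[str, frozenset[str]] = {}
        for gene, groups in (entries or {}).items():
            gs = frozenset(groups)
            if not gs:
                raise ValidationError(f"gene {gene!r} has an empty group set")
            if any(not g for g in gs):
                raise ValidationError(f"gene {gene!r} has an empty group label")
            self._entries[gene] = gs

    def groups(self, gene: str) -> frozenset[str]:
        return self._entries.get(gene, frozenset({UNANNOTATED}))

    def genes_in(self, group: str) -> frozenset[str]:
        return frozenset(g for g, gs in self._entries.items() if group in gs)

    @property
    def entries(self) -> dict[str, frozenset[str]]:
        return dict(self._entries)

    def group_labels(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self._entries.values():
            out |= gs
        return frozenset(out)

    def __contains__(self, gene: str) -> bool:
        return gene in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AnnotationMap) and self._entries == other._entries


def _split_row(line: str, n_cols: int, lineno: int, path: Path) -> list[str]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) != n_cols:
        raise FormatError(
            f"{path}:{lineno}: expected {n_cols} tab-separated columns, "
            f"got {len(parts)}: {line.rstrip()!r}"
        )
    return parts


def read_network_series(path: str | Path, directed: bool) -> NetworkSeries:
    """Parse a long-format network-series TSV into a :class:`NetworkSeries`.

    Duplicate ``(time, source, target)`` rows are an error; in undirected mode
    a pair stored in both orientations at one timepoint is also an error.
    """
    path = Path(path)
    per_time: dict[str, dict[tuple[str, str], float]] = {}
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise FormatError(f"{path}:1: empty file, expected header "
                              + "\\t".join(SERIES_HEADER))
        cols = tuple(header.rstrip("\n").split("\t"))
        if cols != SERIES_HEADER:
            raise FormatError(
                f"{path}:1: bad header {header.rstrip()!r}; expected "
                + "\\t".join(SERIES_HEADER)
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            t, u, v, wtext = _split_row(line, 4, lineno, path)
            try:
                w = float(wtext)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: weight {wtext!r} is not a decimal number"
                ) from None
            if not w > 0:
                raise ValidationError(f"{path}:{lineno}: weight must be > 0, got {w}")
            if u == v:
                raise ValidationError(f"{path}:{lineno}: self-loop on {u!r}")
            edges = per_time.setdefault(t, {})
            if (u, v) in edges:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate edge ({t!r}, {u!r}, {v!r})"
                )
            if not directed and (v, u) in edges:
                raise ValidationError(
                    f"{path}:{lineno}: edge {u!r}-{v!r} at {t!r} already stored "
                    f"as {v!r}-{u!r} (undirected mode)"
                )
            edges[(u, v)] = w
    snapshots = [
        NetworkSnapshot.from_edges(t, directed, [(u, v, w) for (u, v), w in e.items()])
        for t, e in per_time.items()
    ]
    return NetworkSeries.from_snapshots(snapshots, directed)


def _format_weight(w: float) -> str:
    return repr(w) if w != int(w) else str(int(w)) + ".0"


def write_network_series(series: NetworkSeries, path: str | Path) -> None:
    """Inverse of :func:`read_network_series`, in canonical row order
    (time order, then sorted endpoint pairs)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(SERIES_HEADER) + "\n")
        for snap in series:
            for u, v, w in sorted(snap.edges):
                fh.write(f"{snap.time_label}\t{u}\t{v}\t{_format_weight(w)}\n")


def read_annotations(path: str | Path) -> AnnotationMap:
    """Parse a two-column ``gene<TAB>group`` TSV; duplicate rows collapse."""
    path = Path(path)
    entries: dict[str, set[str]] = {}
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise FormatError(f"{path}:1: empty file, expected header gene\\tgroup")
        cols = tuple(header.rstrip("\n").split("\t"))
        if cols != ANNOTATION_HEADER:
            raise FormatError(
                f"{path}:1: bad header {header.rstrip()!r}; expected gene\\tgroup"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            gene, group = _split_row(line, 2, lineno, path)
            if not group:
                raise ValidationError(f"{path}:{lineno}: empty group label for {gene!r}")
            if not gene:
                raise ValidationError(f"{path}:{lineno}: empty gene identifier")
            entries.setdefault(gene, set()).add(group)
    return AnnotationMap(entries)


def write_annotations(annotations: AnnotationMap, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene\tgroup\n")
        for gene in sorted(annotations.entries):
            for group in sorted(annotations.groups(gene)):
                fh.write(f"{gene}\t{group}\n")


def _newick_label(label: str) -> str:
    if any(c in label for c in " \t()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def newick_string(tree) -> str:
    """Serialize a layout.ClusterTree to Newick.

    Branch length of a child = parent merge height − child height (leaves sit
    at height 0), so internal-node heights are recoverable from root-to-leaf
    path sums. Left-to-right leaf order in the string equals ``tree.leaf_order``.
    """

    def fmt(node, parent_height: float | None) -> str:
        if node.is_leaf:
            text = _newick_label(node.label)
            height = 0.0
        else:
            text = "(" + ",".join(fmt(c, node.height) for c in node.children) + ")"
            height = node.height
        if parent_height is None:
            return text
        return f"{text}:{parent_height - height:g}"

    return fmt(tree.root, None) + ";"


def write_tree_newick(tree, path: str | Path) -> None:
    """Write a sorting tree (layout.ClusterTree) as Newick."""
    Path(path).write_text(newick_string(tree) + "\n", encoding="utf-8")


def write_snapshot_graphml(snapshot: NetworkSnapshot, path: str | Path) -> None:
    """Export one snapshot to GraphML for interoperability with other viewers."""
    nx.write_graphml(snapshot.graph, str(path))
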
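"""Two-level network construction: gene networks collapsed to functional groups.

A gene-gene edge whose endpoints carry group-label sets S and T contributes

* one count to ``intra_counts[G]`` for every group G shared by both endpoints, and
* one count to ``inter_counts[{G, H}]`` for every distinct unordered pair of
  groups with G from S and H from T.

Under single-membership annotation this makes the conservation law exact:
sum of intra counts + sum of inter counts = number of edges. Group-level
edges are undirected even for directed inputs, and the counts are edge
counts (a distinct-gene variant is available separately).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import GeneLookupError
from .io import AnnotationMap, NetworkSnapshot

__all__ = [
    "GroupedNetwork",
    "ExpandedView",
    "NeighborEntry",
    "aggregate",
    "expand_group",
    "recollapse",
    "gene_neighborhood",
    "interacting_gene_counts",
]


@dataclass(frozen=True)
class GroupedNetwork:
    """Aggregate network whose nodes are group labels.

    ``inter_counts`` keys are sorted 2-tuples of distinct group labels.
    """

    time_label: str
    group_labels: frozenset[str]
    intra_counts: dict[str, int]
    inter_counts: dict[tuple[str, str], int]

    @property
    def total_count(self) -> int:
        return sum(self.intra_counts.values()) + sum(self.inter_counts.values())

    def to_tsv(self, path: str | Path) -> None:
        """Rows ``group_a group_b count``; intra rows have group_a == group_b."""
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("group_a\tgroup_b\tcount\n")
            for g in sorted(self.intra_counts):
                fh.write(f"{g}\t{g}\t{self.intra_counts[g]}\n")
            for (a, b) in sorted(self.inter_counts):
                fh.write(f"{a}\t{b}\t{self.inter_counts[(a, b)]}\n")


@dataclass(frozen=True)
class ExpandedView:
    """Mixed-resolution view: one group opened to gene level, the rest aggregated.

    ``gene_to_group_edges`` counts, per (member gene, other group), the edges
    from that gene into that group. ``gene_to_gene_edges`` are the within-focus
    edges at gene resolution (sorted endpoint pairs). ``boundary_edges`` keeps
    the raw member/non-member edge list so the view can be re-collapsed without
    consulting the original snapshot.
    """

    focus_group: str
    member_genes: frozenset[str]
    gene_to_group_edges: dict[tuple[str, str], int]
    gene_to_gene_edges: frozenset[tuple[str, str]]
    collapsed: GroupedNetwork
    boundary_edges: frozenset[tuple[str, str]]
    time_label: str


@dataclass(frozen=True)
class NeighborEntry:
    """One incident edge of a focal gene, with the neighbor's group labels.

    ``direction`` is ``"out"``/``"in"`` for directed snapshots, ``None`` for
    undirected ones; a bidirectional neighbor yields two entries.
    """

    neighbor: str
    groups: frozenset[str]
    weight: float
    direction: str | None


def _pair_contribs(
    groups_u: frozenset[str], groups_v: frozenset[str]
) -> tuple[set[str], set[tuple[str, str]]]:
    """Intra groups and distinct unordered inter pairs one edge contributes to."""
    intra = set(groups_u & groups_v)
    inter = {
        tuple(sorted((g, h)))
        for g in groups_u
        for h in groups_v
        if g != h
    }
    return intra, inter  # type: ignore[return-value]


def _count_edges(
    edges: Iterable[tuple[str, str]],
    annotations: AnnotationMap,
) -> tuple[Counter, Counter]:
    intra: Counter = Counter()
    inter: Counter = Counter()
    for u, v in edges:
        gi, ge = _pair_contribs(annotations.groups(u), annotations.groups(v))
        intra.update(gi)
        inter.update(ge)
    return intra, inter


def aggregate(snapshot: NetworkSnapshot, annotations: AnnotationMap) -> GroupedNetwork:
    """Collapse a gene network to its group-level aggregate (direction discarded)."""
    edges = [(u, v) for u, v, _w in snapshot.edges]
    intra, inter = _count_edges(edges, annotations)
    labels = set(intra) | {g for pair in inter for g in pair}
    for gene in snapshot.nodes:
        labels |= annotations.groups(gene)
    return GroupedNetwork(
        time_label=snapshot.time_label,
        group_labels=frozenset(labels),
        intra_counts=dict(intra),
        inter_counts=dict(inter),
    )


def expand_group(
    snapshot: NetworkSnapshot, annotations: AnnotationMap, group: str
) -> ExpandedView:
    """Open one group to gene resolution, keeping the others aggregated."""
    if group not in annotations.group_labels() and group != "unannotated":
        raise GeneLookupError(group)
    members = frozenset(
        g for g in snapshot.nodes if group in annotations.groups(g)
    )
    gene_to_group: Counter = Counter()
    gene_gene: set[tuple[str, str]] = set()
    boundary: set[tuple[str, str]] = set()
    outside: list[tuple[str, str]] = []
    for u, v, _w in snapshot.edges:
        u_in, v_in = u in members, v in members
        if u_in and v_in:
            gene_gene.add(tuple(sorted((u, v))))  # type: ignore[arg-type]
        elif u_in or v_in:
            m, x = (u, v) if u_in else (v, u)
            boundary.add((m, x))
            for h in annotations.groups(x):
                if h != group:
                    gene_to_group[(m, h)] += 1
        else:
            outside.append((u, v))
    intra, inter = _count_edges(outside, annotations)
    intra.pop(group, None)
    for pair in [p for p in inter if group in p]:
        del inter[pair]
    other_labels = {
        lab
        for gene in snapshot.nodes - members
        for lab in annotations.groups(gene)
        if lab != group
    }
    collapsed = GroupedNetwork(
        time_label=snapshot.time_label,
        group_labels=frozenset(other_labels),
        intra_counts=dict(intra),
        inter_counts=dict(inter),
    )
    return ExpandedView(
        focus_group=group,
        member_genes=members,
        gene_to_group_edges=dict(gene_to_group),
        gene_to_gene_edges=frozenset(gene_gene),
        collapsed=collapsed,
        boundary_edges=frozenset(boundary),
        time_label=snapshot.time_label,
    )


def recollapse(view: ExpandedView, annotations: AnnotationMap) -> GroupedNetwork:
    """Fold the focus group back in, reconstructing the full aggregate from the
    view's own fields (collapsed remainder + within-focus + boundary edges)."""
    intra = Counter(view.collapsed.intra_counts)
    inter = Counter(view.collapsed.inter_counts)
    member_edges = list(view.gene_to_gene_edges) + list(view.boundary_edges)
    add_intra, add_inter = _count_edges(member_edges, annotations)
    intra.update(add_intra)
    inter.update(add_inter)
    labels = set(view.collapsed.group_labels) | {view.focus_group}
    for gene in view.member_genes:
        labels |= annotations.groups(gene)
    return GroupedNetwork(
        time_label=view.time_label,
        group_labels=frozenset(labels),
        intra_counts=dict(intra),
        inter_counts=dict(inter),
    )


def gene_neighborhood(
    snapshot: NetworkSnapshot, annotations: AnnotationMap, gene: str
) -> list[NeighborEntry]:
    """Spoke view of one gene: each incident edge with the neighbor's groups.

    Entry count equals the gene's (total) degree.
    """
    if gene not in snapshot.graph:
        raise GeneLookupError(gene)
    g = snapshot.graph
    entries: list[NeighborEntry] = []
    if snapshot.directed:
        for n in g.successors(gene):
            entries.append(
                NeighborEntry(n, annotations.groups(n), g.edges[gene, n]["weight"], "out")
            )
        for n in g.predecessors(gene):
            entries.append(
                NeighborEntry(n, annotations.groups(n), g.edges[n, gene]["weight"], "in")
            )
    else:
        for n in g.neighbors(gene):
            entries.append(
                NeighborEntry(n, annotations.groups(n), g.edges[gene, n]["weight"], None)
            )
    entries.sort(key=lambda e: (e.neighbor, e.direction or ""))
    return entries


def interacting_gene_counts(
    snapshot: NetworkSnapshot, annotations: AnnotationMap
) -> dict[tuple[str, str], int]:
    """Alternative group-pair statistic: number of distinct genes participating
    in at least one edge crossing the pair, rather than the edge count."""
    participants: dict[tuple[str, str], set[str]] = {}
    for u, v, _w in snapshot.edges:
        _intra, inter = _pair_contribs(annotations.groups(u), annotations.groups(v))
        for pair in inter:
            participants.setdefault(pair, set()).update((u, v))
    return {pair: len(genes) for pair, genes in sorted(participants.items())}
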
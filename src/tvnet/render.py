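"""Static SVG views of time-varying networks.

Four views are emitted, mirroring the interactive originals as declarative
vector documents:

* one-level circle view — all genes on a circle, edges as chords whose
  opacity encodes weight; an optional focus node switches to the directed
  highlight palette (in-edges red, out-edges green, bidirectional cyan) and
  restricts the drawing to the focus node's neighborhood;
* two-level group view — group nodes on a circle, inter-group edge stroke
  width affine in the cross-group interaction count;
* expanded view — one group opened to gene resolution inside its arc;
* stack view — per-entity degree bands stacked over the time axis, the top
  envelope tracing total activity.

All geometry is rounded to 3 decimal places so frames of a series diff
cleanly at byte level. Documents are plain SVG 1.1; machine-readable
``data-*`` attributes (gene, group, counts, band values) accompany every
glyph so the output can be checked — or post-processed — by parsing the XML.
"""

from __future__ import annotations

import math
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .dynamics import (
    DegreeMatrix,
    classify_incident_edges,
    filter_edges,
    isolate_node,
)
from .errors import UsageError, ValidationError
from .grouping import ExpandedView, GroupedNetwork
from .io import NetworkSeries, NetworkSnapshot
from .layout import CircularLayout

__all__ = [
    "StyleConfig",
    "VectorDocument",
    "opacity_for_weight",
    "render_circle",
    "render_grouped",
    "render_stack",
    "render_series",
    "CLUSTER_PALETTE",
    "DIRECTED_PALETTE",
]

# 20-color qualitative palette (matplotlib "tab20"), cycled for k > 20 clusters.
CLUSTER_PALETTE = (
    "#1f77b4", "#aec7e8", "#ff7f0e", "#ffbb78", "#2ca02c", "#98df8a",
    "#d62728", "#ff9896", "#9467bd", "#c5b0d5", "#8c564b", "#c49c94",
    "#e377c2", "#f7b6d2", "#7f7f7f", "#c7c7c7", "#bcbd22", "#dbdb8d",
    "#17becf", "#9edae5",
)

# Fixed highlight palette for directed incident edges of a focus node.
DIRECTED_PALETTE = {"in": "red", "out": "green", "bidirectional": "cyan"}

_EDGE_COLOR = "#444444"


@dataclass(frozen=True)
class StyleConfig:
    """Declarative render parameters replacing the original's GUI controls.

    ``label_whitelist=None`` shows every label; an explicit set shows only
    those labels (the empty set hides all). ``series_opacity_norm`` switches
    edge-opacity normalization from per-snapshot (maximal within-frame
    contrast) to series-global (cross-frame comparability).
    """

    min_edge_weight: float = 0.0
    edge_opacity_range: tuple[float, float] = (0.2, 1.0)
    node_size_range: tuple[float, float] = (4.0, 16.0)
    size_by_degree: bool = False
    label_whitelist: frozenset[str] | None = None
    font_size: float = 10.0
    canvas_size: int = 600
    edge_width_range: tuple[float, float] = (1.0, 8.0)
    series_opacity_norm: bool = False

    def __post_init__(self) -> None:
        omin, omax = self.edge_opacity_range
        if not (0.0 <= omin <= omax <= 1.0):
            raise ValidationError(f"bad edge_opacity_range {self.edge_opacity_range}")
        smin, smax = self.node_size_range
        if not (0.0 < smin <= smax):
            raise ValidationError(f"bad node_size_range {self.node_size_range}")
        if self.min_edge_weight < 0:
            raise ValidationError("min_edge_weight must be >= 0")
        if self.font_size <= 0 or self.canvas_size <= 0:
            raise ValidationError("font_size and canvas_size must be positive")
        wmin, wmax = self.edge_width_range
        if not (0.0 < wmin <= wmax):
            raise ValidationError(f"bad edge_width_range {self.edge_width_range}")


class VectorDocument:
    """Thin wrapper over an SVG element tree with string/file serialization."""

    def __init__(self, root: ET.Element) -> None:
        self.root = root

    def to_string(self) -> str:
        return ET.tostring(self.root, encoding="unicode")

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            '<?xml version="1.0" encoding="UTF-8"?>\n' + self.to_string() + "\n",
            encoding="utf-8",
        )

    def find_all(self, cls: str) -> list[ET.Element]:
        return [e for e in self.root.iter() if e.get("class") == cls]


def _fmt(x: float) -> str:
    """Geometry formatting: fixed 3 decimals, no negative zero."""
    s = f"{x:.3f}"
    return "0.000" if s == "-0.000" else s


def _svg_root(width: float, height: float) -> ET.Element:
    return ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "width": _fmt(width),
            "height": _fmt(height),
            "viewBox": f"0 0 {_fmt(width)} {_fmt(height)}",
        },
    )


def opacity_for_weight(
    weight: float, w_min: float, w_max: float, style: StyleConfig
) -> float:
    """Affine map of ``weight`` from [w_min, w_max] onto the opacity range.

    A degenerate range (w_min == w_max) maps to the maximum opacity.
    """
    if not (w_min <= weight <= w_max):
        raise ValidationError(
            f"weight {weight} outside normalization range [{w_min}, {w_max}]"
        )
    omin, omax = style.edge_opacity_range
    if w_min == w_max:
        return omax
    return omin + (omax - omin) * (weight - w_min) / (w_max - w_min)


def _xy(angle: float, radius: float, cx: float, cy: float) -> tuple[float, float]:
    """Angle (radians clockwise from 12 o'clock) to canvas coordinates."""
    return cx + radius * math.sin(angle), cy - radius * math.cos(angle)


def _fit_radius(style: StyleConfig, labels: Iterable[str]) -> float:
    """Radial padding so labels and node glyphs fit the canvas (constant
    per-character width estimate, no font metrics)."""
    max_label = max((len(l) for l in labels), default=0)
    pad = style.node_size_range[1] + style.font_size * (0.62 * max_label + 1.0)
    return max(style.canvas_size / 2.0 - pad, style.canvas_size * 0.15)


def _weight_range(edges: Iterable[tuple[str, str, float]]) -> tuple[float, float]:
    ws = [w for *_uv, w in edges]
    if not ws:
        return (0.0, 0.0)
    return min(ws), max(ws)


def render_circle(
    snapshot: NetworkSnapshot,
    layout: CircularLayout,
    style: StyleConfig = StyleConfig(),
    focus_node: str | None = None,
    weight_range: tuple[float, float] | None = None,
) -> VectorDocument:
    """One-level circle view of a single snapshot.

    Node positions come solely from ``layout`` so frames of a series share
    identical coordinates. With ``focus_node`` on a directed snapshot the
    view is restricted to the focus neighborhood and incident edges take the
    in/out/bidirectional highlight colors.
    """
    missing = snapshot.nodes - set(layout.order)
    if missing:
        raise ValidationError(f"layout missing nodes: {sorted(missing)[:5]}")
    drawn = filter_edges(snapshot, style.min_edge_weight)
    edge_colors: dict[tuple[str, str], str] = {}
    if focus_node is not None:
        if snapshot.directed:
            drawn = filter_edges(
                isolate_node(snapshot, focus_node), style.min_edge_weight
            )
            cls = classify_incident_edges(drawn, focus_node)
            for n in cls.in_only:
                edge_colors[(n, focus_node)] = DIRECTED_PALETTE["in"]
            for n in cls.out_only:
                edge_colors[(focus_node, n)] = DIRECTED_PALETTE["out"]
            for n in cls.bidirectional:
                edge_colors[(n, focus_node)] = DIRECTED_PALETTE["bidirectional"]
                edge_colors[(focus_node, n)] = DIRECTED_PALETTE["bidirectional"]
        else:
            drawn = filter_edges(
                isolate_node(snapshot, focus_node), style.min_edge_weight
            )

    size = float(style.canvas_size)
    cx = cy = size / 2.0
    r = _fit_radius(style, layout.order)
    root = _svg_root(size, size)
    root.set("data-time", snapshot.time_label)

    if weight_range is None:
        weight_range = _weight_range(drawn.edges)
    w_lo, w_hi = weight_range

    edges_g = ET.SubElement(root, "g", {"class": "edges"})
    for u, v, w in sorted(drawn.edges):
        x1, y1 = _xy(layout.angles[u], r, cx, cy)
        x2, y2 = _xy(layout.angles[v], r, cx, cy)
        attrs = {
            "class": "edge",
            "x1": _fmt(x1), "y1": _fmt(y1), "x2": _fmt(x2), "y2": _fmt(y2),
            "stroke": edge_colors.get((u, v), _EDGE_COLOR),
            "stroke-opacity": _fmt(opacity_for_weight(w, w_lo, w_hi, style)),
            "data-source": u,
            "data-target": v,
            "data-weight": _fmt(w),
        }
        ET.SubElement(edges_g, "line", attrs)

    nodes_g = ET.SubElement(root, "g", {"class": "nodes"})
    visible = drawn.nodes if focus_node is not None else snapshot.nodes
    for g in layout.order:
        if g not in visible:
            continue
        x, y = _xy(layout.angles[g], r, cx, cy)
        ET.SubElement(
            nodes_g,
            "circle",
            {
                "class": "node",
                "cx": _fmt(x), "cy": _fmt(y),
                "r": _fmt(layout.node_size[g] / 2.0),
                "fill": CLUSTER_PALETTE[layout.color[g] % len(CLUSTER_PALETTE)],
                "data-gene": g,
            },
        )

    labels_g = ET.SubElement(root, "g", {"class": "labels"})
    for g in layout.order:
        if g not in visible:
            continue
        if style.label_whitelist is not None and g not in style.label_whitelist:
            continue
        lx, ly = _xy(layout.angles[g], r + style.node_size_range[1], cx, cy)
        el = ET.SubElement(
            labels_g,
            "text",
            {
                "class": "label",
                "x": _fmt(lx), "y": _fmt(ly),
                "font-size": _fmt(style.font_size),
                "text-anchor": "middle",
                "data-gene": g,
            },
        )
        el.text = g
    return VectorDocument(root)


def _group_positions(
    labels: Sequence[str], style: StyleConfig
) -> tuple[dict[str, tuple[float, float]], dict[str, float], float, float, float]:
    size = float(style.canvas_size)
    cx = cy = size / 2.0
    r = _fit_radius(style, labels)
    n = max(len(labels), 1)
    angles = {g: i * 2.0 * math.pi / n for i, g in enumerate(labels)}
    pos = {g: _xy(a, r, cx, cy) for g, a in angles.items()}
    return pos, angles, r, cx, cy


def _width_for_count(count: int, lo: int, hi: int, style: StyleConfig) -> float:
    wmin, wmax = style.edge_width_range
    if hi == lo:
        return wmax
    return wmin + (wmax - wmin) * (count - lo) / (hi - lo)


def render_grouped(
    grouped: GroupedNetwork | ExpandedView,
    style: StyleConfig = StyleConfig(),
) -> VectorDocument:
    """Two-level group view; an :class:`ExpandedView` additionally draws the
    focus group's member genes inside that group's arc."""
    expanded = isinstance(grouped, ExpandedView)
    if expanded:
        view: ExpandedView = grouped  # type: ignore[assignment]
        group_labels = sorted(view.collapsed.group_labels | {view.focus_group})
        inter = dict(view.collapsed.inter_counts)
        intra = dict(view.collapsed.intra_counts)
        time_label = view.time_label
    else:
        gn: GroupedNetwork = grouped  # type: ignore[assignment]
        group_labels = sorted(gn.group_labels)
        inter = dict(gn.inter_counts)
        intra = dict(gn.intra_counts)
        time_label = gn.time_label
    if not group_labels:
        raise UsageError("render_grouped requires at least one group")

    pos, angles, r, cx, cy = _group_positions(group_labels, style)
    size = float(style.canvas_size)
    root = _svg_root(size, size)
    root.set("data-time", time_label)

    counts_for_scale = list(inter.values())
    if expanded:
        counts_for_scale += list(view.gene_to_group_edges.values())
    lo = min(counts_for_scale, default=0)
    hi = max(counts_for_scale, default=0)

    edges_g = ET.SubElement(root, "g", {"class": "group-edges"})
    for (a, b), count in sorted(inter.items()):
        (x1, y1), (x2, y2) = pos[a], pos[b]
        ET.SubElement(
            edges_g,
            "line",
            {
                "class": "group-edge",
                "x1": _fmt(x1), "y1": _fmt(y1), "x2": _fmt(x2), "y2": _fmt(y2),
                "stroke": _EDGE_COLOR,
                "stroke-width": _fmt(_width_for_count(count, lo, hi, style)),
                "data-group-a": a,
                "data-group-b": b,
                "data-count": str(count),
            },
        )

    nodes_g = ET.SubElement(root, "g", {"class": "group-nodes"})
    for i, g in enumerate(group_labels):
        if expanded and g == view.focus_group:
            continue
        x, y = pos[g]
        ET.SubElement(
            nodes_g,
            "circle",
            {
                "class": "group-node",
                "cx": _fmt(x), "cy": _fmt(y),
                "r": _fmt(style.node_size_range[1]),
                "fill": CLUSTER_PALETTE[i % len(CLUSTER_PALETTE)],
                "data-group": g,
                "data-intra": str(intra.get(g, 0)),
            },
        )
        if style.label_whitelist is None or g in style.label_whitelist:
            lx, ly = _xy(angles[g], r + style.node_size_range[1] * 1.5, cx, cy)
            el = ET.SubElement(
                root,
                "text",
                {
                    "class": "label",
                    "x": _fmt(lx), "y": _fmt(ly),
                    "font-size": _fmt(style.font_size),
                    "text-anchor": "middle",
                    "data-group": g,
                },
            )
            el.text = g

    if expanded:
        members = sorted(view.member_genes)
        focus_angle = angles[view.focus_group]
        arc = 2.0 * math.pi / max(len(group_labels), 1)
        gene_pos: dict[str, tuple[float, float]] = {}
        genes_g = ET.SubElement(root, "g", {"class": "member-genes"})
        for j, m in enumerate(members):
            a = focus_angle + arc * ((j + 1) / (len(members) + 1) - 0.5)
            gene_pos[m] = _xy(a, r, cx, cy)
        member_edges_g = ET.SubElement(root, "g", {"class": "member-edges"})
        for (m, h), count in sorted(view.gene_to_group_edges.items()):
            (x1, y1), (x2, y2) = gene_pos[m], pos[h]
            ET.SubElement(
                member_edges_g,
                "line",
                {
                    "class": "gene-group-edge",
                    "x1": _fmt(x1), "y1": _fmt(y1), "x2": _fmt(x2), "y2": _fmt(y2),
                    "stroke": _EDGE_COLOR,
                    "stroke-width": _fmt(_width_for_count(count, lo, hi, style)),
                    "data-gene": m,
                    "data-group": h,
                    "data-count": str(count),
                },
            )
        for (u, v) in sorted(view.gene_to_gene_edges):
            (x1, y1), (x2, y2) = gene_pos[u], gene_pos[v]
            ET.SubElement(
                member_edges_g,
                "line",
                {
                    "class": "gene-gene-edge",
                    "x1": _fmt(x1), "y1": _fmt(y1), "x2": _fmt(x2), "y2": _fmt(y2),
                    "stroke": _EDGE_COLOR,
                    "stroke-width": _fmt(style.edge_width_range[0]),
                    "data-source": u,
                    "data-target": v,
                },
            )
        for m in members:
            x, y = gene_pos[m]
            ET.SubElement(
                genes_g,
                "circle",
                {
                    "class": "gene-node",
                    "cx": _fmt(x), "cy": _fmt(y),
                    "r": _fmt(style.node_size_range[0]),
                    "fill": CLUSTER_PALETTE[
                        group_labels.index(view.focus_group) % len(CLUSTER_PALETTE)
                    ],
                    "data-gene": m,
                },
            )
            if style.label_whitelist is None or m in style.label_whitelist:
                el = ET.SubElement(
                    root,
                    "text",
                    {
                        "class": "label",
                        "x": _fmt(x), "y": _fmt(y - style.node_size_range[0] - 2.0),
                        "font-size": _fmt(style.font_size * 0.8),
                        "text-anchor": "middle",
                        "data-gene": m,
                    },
                )
                el.text = m
    return VectorDocument(root)


def render_stack(
    dm: DegreeMatrix,
    selection: Iterable[str] | None = None,
    style: StyleConfig = StyleConfig(),
) -> VectorDocument:
    """Stacked degree bands over the time axis.

    Bands are stacked base-first in descending total degree (ties
    lexicographic). Band polygons live in data coordinates (x = timepoint
    index, y = cumulative degree) inside a single transformed group, so the
    stacking geometry can be read back exactly from the ``points``
    attributes; the top envelope at each timepoint equals the column sum of
    the selected rows. Each band carries a ``data-values`` attribute and a
    ``<title>`` child listing its per-timepoint degrees.
    """
    if not dm.entity_labels or not dm.time_labels:
        raise UsageError("render_stack requires a non-empty degree matrix")
    if selection is not None:
        selection = set(selection)
        keep = [e for e in dm.entity_labels if e in selection]
        if not keep:
            raise ValidationError("selection is disjoint from the entity labels")
        dm = dm.select(keep)

    totals = dm.frame.sum(axis=1)
    order = sorted(dm.entity_labels, key=lambda e: (-totals[e], e))
    frame = dm.frame.loc[order]
    times = dm.time_labels
    n_t = len(times)
    col_sums = frame.sum(axis=0)
    y_max = float(col_sums.max()) or 1.0

    size = float(style.canvas_size)
    margin = 4.0 * style.font_size
    plot_w = size - 2 * margin
    plot_h = size - 2 * margin
    sx = plot_w / max(n_t - 1, 1)
    sy = plot_h / y_max

    root = _svg_root(size, size)
    root.set("data-entities", str(len(order)))
    # Data-space group: x in [0, n_t-1], y in degrees, y up.
    gt = ET.SubElement(
        root,
        "g",
        {
            "class": "stack",
            "transform": f"translate({_fmt(margin)},{_fmt(size - margin)}) "
            f"scale({_fmt(sx)},{_fmt(-sy)})",
        },
    )
    cumulative = [0.0] * n_t
    for ci, entity in enumerate(order):
        vals = [float(v) for v in frame.loc[entity]]
        lower = list(cumulative)
        upper = [lo + v for lo, v in zip(lower, vals)]
        pts = [(i, lower[i]) for i in range(n_t)] + [
            (i, upper[i]) for i in range(n_t - 1, -1, -1)
        ]
        band = ET.SubElement(
            gt,
            "polygon",
            {
                "class": "band",
                "points": " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in pts),
                "fill": CLUSTER_PALETTE[ci % len(CLUSTER_PALETTE)],
                "data-entity": entity,
                "data-values": ",".join(str(int(v)) for v in vals),
            },
        )
        title = ET.SubElement(band, "title")
        title.text = "; ".join(
            f"{entity} @ {t}: degree {int(v)}" for t, v in zip(times, vals)
        )
        cumulative = upper

    axis = ET.SubElement(root, "g", {"class": "axis"})
    ET.SubElement(
        axis,
        "line",
        {
            "class": "axis-x",
            "x1": _fmt(margin), "y1": _fmt(size - margin),
            "x2": _fmt(size - margin), "y2": _fmt(size - margin),
            "stroke": "black",
        },
    )
    for i, t in enumerate(times):
        el = ET.SubElement(
            axis,
            "text",
            {
                "class": "tick",
                "x": _fmt(margin + i * sx),
                "y": _fmt(size - margin + 1.5 * style.font_size),
                "font-size": _fmt(style.font_size * 0.9),
                "text-anchor": "middle",
                "data-time": t,
            },
        )
        el.text = t
    return VectorDocument(root)


_SAFE = re.compile(r"[^A-Za-z0-9._-]")


def _safe_label(label: str) -> str:
    return _SAFE.sub("_", label)


def render_series(
    series: NetworkSeries,
    layout: CircularLayout,
    style: StyleConfig = StyleConfig(),
    out_dir: str | Path = ".",
) -> list[Path]:
    """One SVG per snapshot with identical node coordinates across frames.

    Filenames embed the time label (``net_<label>.svg``); the returned paths
    are in time order. With ``style.series_opacity_norm`` edge opacity is
    normalized over the whole series instead of per frame.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wrange = None
    if style.series_opacity_norm:
        all_edges = [e for snap in series for e in filter_edges(
            snap, style.min_edge_weight).edges]
        wrange = _weight_range(all_edges)
    paths: list[Path] = []
    for i, snap in enumerate(series):
        doc = render_circle(snap, layout, style, weight_range=wrange)
        path = out_dir / f"net_{i:03d}_{_safe_label(snap.time_label)}.svg"
        doc.write(path)
        paths.append(path)
    return paths
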
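# Methods

This note records the models, conventions, and open design choices behind
`tvnet`, in the order data flows through the package.

## Data model

A *network series* is an ordered list of weighted snapshots over one node
universe with uniform directedness. Weights are positive, unitless
interaction strengths as produced by a network-inference method; a zero
weight is the same as an absent edge and is rejected on input rather than
stored. Self-loops are rejected. Genes with no edges at a timepoint remain
in the universe with degree 0 — keeping the axis of the stack view and the
circle layout identical across time is what makes frames comparable.

Time labels are opaque strings. If every label parses as a number the
series sorts numerically, otherwise lexicographically; this lets one code
path serve both timepoint axes ("1"…"24") and condition axes ("S1", "T4",
"T4R"). Lifetime intervals are computed on 0-based snapshot indices and
converted to labels only in user-facing exports, because label arithmetic
is undefined.

## Thresholding and degree

The minimum-edge-weight filter keeps edges with `weight ≥ τ`: an edge
strictly *below* the minimum disappears. Degree is the **count** of
surviving incident edges, not a weight sum — stack-view heights are integer
degrees per timepoint. For directed series, `total` degree counts a
bidirectionally stored pair once per direction; `in`/`out` modes are
rejected for undirected series rather than silently coerced.

A gene annotated to several groups contributes its full degree to every
group, so group totals can exceed gene totals under multi-membership
annotation. This is deliberate: GO is a multi-assignment vocabulary and
silently dropping annotations would misrepresent group activity. The
conservation law (group column sums = gene column sums) therefore holds
exactly under single-membership annotation, and tests state it that way.

## Group aggregation

An edge whose endpoints carry group sets S and T adds one count to
`intra[G]` for each shared group G ∈ S∩T and one count to `inter[{G,H}]`
for each *distinct unordered* pair with G ∈ S, H ∈ T, G ≠ H. Group-level
edges are undirected even for directed inputs, matching how group graphs
are conventionally drawn with thickness-coded, direction-free edges. We
count gene–gene **edges** crossing a pair, not distinct genes: edge counts
make the conservation law Σ intra + Σ inter = |E| exact for
single-membership annotation. The distinct-gene variant is available as
`grouping.interacting_gene_counts` for analysts who want the other
statistic.

`expand_group` keeps the raw member-incident edge list (`boundary_edges`)
on the view so that re-collapsing the focus group is a structural
computation on the view's own fields; the expand → recollapse → aggregate
identity is checked in tests including multi-membership annotation.

## Circular layout

The order of genes on the circle comes from agglomerative clustering of the
**time-union network** (an edge is present if it passes the threshold at
any timepoint): one order for the series, fixed node positions across
frames.

Pairwise similarity is `s = (2·J1 + J2)/3`, with `J1` the Jaccard
coefficient of closed one-step neighbor sets (each gene's set includes
itself, so directly connected genes are similar even without common
neighbors) and `J2` the Jaccard coefficient of radius-2 neighborhoods.
`J1` alone is the natural objective-aligned signal, but it saturates on
sparse graphs: two members of the same sparse module that happen to share
no direct neighbor get `J1 = 0`, exactly like an unrelated pair, and
average linkage then has no basis to keep the module together. The
two-step term resolves those ties — a connected module of moderate density
links any two members within a few hops, while genes of different modules
stay disjoint at radius 2 when cross edges are rare. The 2:1 weighting
keeps the one-step term dominant; we did not explore the weighting beyond
observing that the pure one-step form is insufficient (see Limitations).

Dissimilarity `1 − s` feeds scipy's average-linkage agglomeration.
Determinism is imposed at two points:

* **leaf order** — at every merge the subtree whose lexicographically
  smallest leaf is smaller goes on the left;
* **isolated genes** — genes with no edge in the union network carry no
  neighborhood signal at all, so they are appended after the clustered
  genes in lexicographic order, joined at the root height (never below it,
  preserving height monotonicity toward the root).

`locality_score` is the explicit objective the order is judged by: the sum
over edges of the circular slot distance `min(|i−j|, n−|i−j|)`. The
clustering is a heuristic, not a crossing minimizer (that problem is
NP-hard); on ≤8-node graphs we bound it empirically at ≤1.5× the exhaustive
optimum, a property of this heuristic only.

Cluster colors come from cutting the tree into k subtrees by repeatedly
splitting the forest root with the largest merge height (ties: earlier
merge first); clusters are numbered by first appearance in leaf order.
Angles start at 12 o'clock and increase clockwise with equal spacing
2π/n — a convention that has to be stated because nothing upstream fixes
it.

## Rendering

SVG 1.1, geometry rounded to 3 decimals so frames diff at byte level; every
glyph carries `data-*` attributes (gene, group, weight, counts, band
values) making documents checkable by XML parsing. Conventions:

* edge opacity is affine in weight over `[w_min, w_max] → [o_min, o_max]`;
  a degenerate weight range maps to `o_max`. Normalization is
  **per-snapshot** by default (maximal within-frame contrast) with a style
  switch for series-global normalization (cross-frame comparability) —
  both are legitimate readings and the choice is explicit;
* group-edge stroke width is affine in the cross-group count over the
  style's width range, degenerate range → maximum width;
* stack bands are polygons in *data coordinates* (x = timepoint index,
  y = cumulative degree) inside a single scaled group, stacked base-first
  by descending total degree (ties lexicographic), so the envelope/column
  equalities can be asserted on the output geometry itself;
* labels: `None` whitelist = all labels, empty set = none; canvas fit uses
  a constant per-character width estimate (no font metrics by design);
* focus mode on a directed snapshot restricts the view to the focus gene's
  incident subnetwork and colors edges red/green/cyan for
  in/out/bidirectional neighbors.

## Synthetic generator

The generator emulates the *shape* of periodic cell-cycle network data —
modules of genes whose interactions are confined to recurring phase
windows — not expression values and not any inference algorithm. Genes are
partitioned into near-equal modules (remainder to early modules); each
within-module pair is sampled once per series at the within-module density,
cross pairs at the cross density; a sampled edge is active exactly during
its module's windows (cross edges: the merged union of both modules'
windows, abutting intervals merged so ground-truth intervals are maximal
runs, comparable to `edge_lifetimes` output). Weights are redrawn per
active timepoint from uniform (a, b], so chord opacity varies frame to
frame. A single seeded NumPy generator with a documented draw order (pairs
in lexicographic order, then timepoint-major weight draws) makes output
bit-reproducible; in directed mode each sampled pair receives one direction
by a fair coin from the same stream.

The cell-cycle preset plants 60 genes, 3 modules ("G1-like", "S-like",
"G2M-like"), 24 timepoints = two cycles of 12, each module active in the
same 4-timepoint phase of both cycles. Densities are 0.6 within-module and
0.02 cross-module: mean within-degree ≈ 11 against mean cross-degree
≈ 0.8. The contrast is what makes the planted structure *identifiable* —
module membership can only be recovered from realized edges, and a gene
whose sampled cross edges rivaled its within edges would genuinely belong
to the other module as far as any graph statistic is concerned. At
substantially lower within-density (e.g. 0.3) such genes occur in a
sizable fraction of seeds and module recovery is impossible in principle,
not just for this heuristic.

What passing tests on generated data do **not** show: real inferred
networks have hub-dominated degree distributions, weights with structured
noise rather than i.i.d. uniform draws, modules that overlap, and edges
that drift in and out gradually rather than switching with their module.
Recovery rates measured here are properties of the planted model.

## Numerical and degenerate-input choices

* Duplicate edge rows, reversed duplicates in undirected mode, self-loops,
  and non-positive weights are hard errors naming the offending line — a
  silent merge would corrupt degree counts downstream.
* Newick branch length = parent height − child height (leaves at height 0);
  a single-leaf tree serializes as `A;`. Round-trips are tested through an
  independent third-party parser.
* Weight serialization uses Python float repr, so write∘read is the
  identity on files the writer produced (canonical row order: time, then
  sorted endpoints).
* Degenerate affine maps (equal weights, equal counts, equal degrees) pick
  the maximum of the target range.
* `k_colors` must lie in [1, n]; cutting a forest never tries to split a
  leaf.

## Problem sizes

Default test and acceptance runs use the 60-gene preset series (24
snapshots, ~2–3k edge records), 20-seed recovery sweeps, 8-node graphs for
the 100-order locality oracle, and 6-node graphs for the exhaustive
5!-permutation optimum — sizes chosen so the exhaustive oracles stay exact
and the full suite runs in seconds while every code path is exercised at
realistic density.

## Known limitations

* The leaf-ordering heuristic has no approximation guarantee; the 1.5×
  bound is an empirical observation on small graphs.
* The 2:1:… similarity weighting was fixed by argument, not swept; other
  blends may order very sparse or very dense graphs better.
* Group-level views discard direction; a directed group statistic would
  need a different conservation law.
* Canvas fitting estimates text extent as a constant per character; long
  labels in small canvases can still collide visually (the geometry
  contracts tested are unaffected).
* No statistical test for "significant rewiring" is provided — lifetimes
  and profiles are descriptive.
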
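"""SVG output: element counts, styling rules, and geometry conservation."""

from __future__ import annotations

import xml.etree.ElementTree as ET

import pytest

from tvnet import dynamics, layout as tvlayout, render
from tvnet.errors import UsageError, ValidationError
from tvnet.grouping import GroupedNetwork, aggregate, expand_group
from tvnet.io import AnnotationMap
from tvnet.render import StyleConfig

from conftest import random_snapshot, series_of, snap


def layout_for(snapshot):
    return tvlayout.assign_layout(
        tvlayout.cluster_order(series_of(snapshot, directed=snapshot.directed)),
        k_colors=1,
    )


def parse(doc):
    """Round-trip the document through a standard XML parser."""
    return ET.fromstring(doc.to_string())


class TestOpacityForWeight:
    style = StyleConfig(edge_opacity_range=(0.2, 1.0))

    @pytest.mark.parametrize("w,expected", [(0.1, 0.2), (0.9, 1.0), (0.5, 0.6)])
    def test_affine_endpoints_and_midpoint(self, w, expected):
        assert render.opacity_for_weight(w, 0.1, 0.9, self.style) == pytest.approx(expected)

    def test_degenerate_range_maps_to_max(self):
        assert render.opacity_for_weight(0.4, 0.4, 0.4, self.style) == 1.0

    def test_out_of_range_weight_rejected(self):
        with pytest.raises(ValidationError):
            render.opacity_for_weight(1.1, 0.1, 0.9, self.style)

    def test_monotone_in_weight(self):
        ops = [render.opacity_for_weight(w / 10, 0.1, 0.9, self.style)
               for w in range(1, 10)]
        assert ops == sorted(ops)


class TestRenderCircle:
    def test_element_counts_match_snapshot(self):
        s = snap("1", [("a", "b", 0.6), ("b", "c", 0.8), ("a", "c", 0.1)])
        doc = render.render_circle(s, layout_for(s), StyleConfig(min_edge_weight=0.5))
        root = parse(doc)
        assert len([e for e in root.iter() if e.get("class") == "node"]) == 3
        assert len([e for e in root.iter() if e.get("class") == "edge"]) == 2

    def test_empty_whitelist_hides_all_labels(self):
        s = snap("1", [("a", "b", 0.6)])
        doc = render.render_circle(s, layout_for(s),
                                   StyleConfig(label_whitelist=frozenset()))
        assert doc.find_all("label") == []
        doc2 = render.render_circle(s, layout_for(s),
                                    StyleConfig(label_whitelist=frozenset({"a"})))
        assert [e.text for e in doc2.find_all("label")] == ["a"]

    def test_layout_missing_node_rejected(self):
        s = snap("1", [("a", "b", 0.6)])
        small = layout_for(snap("1", [], nodes=["a"]))
        with pytest.raises(ValidationError):
            render.render_circle(s, small)

    def test_focus_highlight_colors_partition_as_classification(self):
        s = snap("1", [("x", "f", 1.0), ("f", "y", 1.0), ("f", "z", 1.0),
                       ("z", "f", 1.0), ("x", "y", 1.0)], directed=True)
        doc = render.render_circle(s, layout_for(s), focus_node="f")
        cls = dynamics.classify_incident_edges(s, "f")  # oracle
        by_color = {"red": set(), "green": set(), "cyan": set()}
        for e in doc.find_all("edge"):
            u, v = e.get("data-source"), e.get("data-target")
            other = v if u == "f" else u
            by_color[e.get("stroke")].add(other)
        assert by_color["red"] == cls.in_only
        assert by_color["green"] == cls.out_only
        assert by_color["cyan"] == cls.bidirectional
        # x-y is not incident to the focus and must not be drawn
        drawn = {(e.get("data-source"), e.get("data-target"))
                 for e in doc.find_all("edge")}
        assert ("x", "y") not in drawn

    def test_opacity_endpoints_hit_style_range(self):
        s = snap("1", [("a", "b", 0.3), ("a", "c", 0.9)])
        doc = render.render_circle(s, layout_for(s),
                                   StyleConfig(edge_opacity_range=(0.25, 0.75)))
        ops = sorted(float(e.get("stroke-opacity")) for e in doc.find_all("edge"))
        assert ops == [0.25, 0.75]

    def test_document_is_well_formed_xml(self, rng):
        s = random_snapshot(rng, 20, 40)
        ET.fromstring(render.render_circle(s, layout_for(s)).to_string())


class TestRenderGrouped:
    def test_stroke_width_monotone_in_count(self):
        gn = GroupedNetwork("1", frozenset("ABC"), {},
                            {("A", "B"): 5, ("A", "C"): 1})
        doc = render.render_grouped(gn)
        widths = {(e.get("data-group-a"), e.get("data-group-b")):
                  float(e.get("stroke-width")) for e in doc.find_all("group-edge")}
        assert widths[("A", "B")] > widths[("A", "C")]

    def test_intra_only_group_draws_no_chords(self):
        gn = GroupedNetwork("1", frozenset("A"), {"A": 4}, {})
        doc = render.render_grouped(gn)
        assert doc.find_all("group-edge") == []
        assert len(doc.find_all("group-node")) == 1

    def test_no_groups_rejected(self):
        with pytest.raises(UsageError):
            render.render_grouped(GroupedNetwork("1", frozenset(), {}, {}))

    def test_stroke_widths_rank_order_matches_counts(self, rng):
        s = random_snapshot(rng, 30, 90)
        am = AnnotationMap({g: {f"grp{rng.randrange(5)}"} for g in s.nodes})
        gn = aggregate(s, am)
        doc = render.render_grouped(gn)
        pairs = []
        for e in doc.find_all("group-edge"):
            key = (e.get("data-group-a"), e.get("data-group-b"))
            pairs.append((gn.inter_counts[key], float(e.get("stroke-width"))))
        by_count = sorted(pairs)
        widths = [w for _c, w in by_count]
        assert widths == sorted(widths)  # oracle: sort counts

    def test_expanded_view_draws_member_genes_and_spokes(self):
        am = AnnotationMap({"m1": {"F"}, "m2": {"F"}, "z": {"Z"}})
        s = snap("1", [("m1", "z", 1.0), ("m1", "m2", 1.0)])
        doc = render.render_grouped(expand_group(s, am, "F"))
        genes = {e.get("data-gene") for e in doc.find_all("gene-node")}
        assert genes == {"m1", "m2"}
        spokes = doc.find_all("gene-group-edge")
        assert [(e.get("data-gene"), e.get("data-group"), e.get("data-count"))
                for e in spokes] == [("m1", "Z", "1")]
        assert len(doc.find_all("gene-gene-edge")) == 1


class TestRenderStack:
    def _dm(self, rows, times):
        import pandas as pd

        from tvnet.dynamics import DegreeMatrix

        return DegreeMatrix(pd.DataFrame(rows, columns=times, dtype=int))

    @staticmethod
    def band_tops(doc):
        """Parse band polygons back into per-timepoint (lower, upper) extents."""
        out = {}
        for band in doc.find_all("band"):
            pts = [tuple(map(float, p.split(","))) for p in band.get("points").split()]
            n_t = len(pts) // 2
            lower = pts[:n_t]
            upper = list(reversed(pts[n_t:]))
            out[band.get("data-entity")] = (lower, upper)
        return out

    def test_envelope_equals_column_sums(self):
        dm = self._dm([[1, 2], [3, 0]], ["t1", "t2"])
        dm.frame.index = ["e1", "e2"]
        doc = render.render_stack(dm)
        bands = self.band_tops(doc)
        top_env = [max(upper[i][1] for _l, upper in bands.values())
                   for i in range(2)]
        assert top_env == [4.0, 2.0]

    def test_selection_reduces_to_single_series(self):
        import pandas as pd
        dm = self._dm([[1, 2], [3, 0]], ["t1", "t2"])
        dm.frame.index = ["e1", "e2"]
        doc = render.render_stack(dm, selection={"e2"})
        bands = self.band_tops(doc)
        assert set(bands) == {"e2"}
        lower, upper = bands["e2"]
        assert [u[1] - l[1] for l, u in zip(lower, upper)] == [3.0, 0.0]

    def test_disjoint_selection_rejected(self):
        dm = self._dm([[1]], ["t1"])
        dm.frame.index = ["e1"]
        with pytest.raises(ValidationError):
            render.render_stack(dm, selection={"nope"})

    def test_bands_are_stacked_without_gaps_and_sum_to_totals(self, rng):
        import pandas as pd
        rows = [[rng.randrange(6) for _ in range(5)] for _ in range(7)]
        dm = self._dm(rows, [f"t{i}" for i in range(5)])
        dm.frame.index = [f"ent{i}" for i in range(7)]
        doc = render.render_stack(dm)
        bands = self.band_tops(doc)
        col_sums = dm.frame.sum(axis=0)
        for i in range(5):
            extents = sorted(
                (lower[i][1], upper[i][1]) for lower, upper in bands.values())
            # adjacent bands abut exactly
            for (lo1, hi1), (lo2, _hi2) in zip(extents, extents[1:]):
                assert hi1 == pytest.approx(lo2)
            assert extents[0][0] == 0.0
            assert extents[-1][1] == pytest.approx(float(col_sums.iloc[i]))

    def test_stacking_order_is_descending_total_then_lexicographic(self):
        dm = self._dm([[1, 1], [2, 2], [1, 1]], ["t1", "t2"])
        dm.frame.index = ["b", "a", "c"]
        doc = render.render_stack(dm)
        entities = [e.get("data-entity") for e in doc.find_all("band")]
        assert entities == ["a", "b", "c"]

    def test_band_value_annotations_present(self):
        dm = self._dm([[1, 2]], ["t1", "t2"])
        dm.frame.index = ["e1"]
        doc = render.render_stack(dm)
        (band,) = doc.find_all("band")
        assert band.get("data-values") == "1,2"
        title = band.find("title")
        assert "e1 @ t2: degree 2" in title.text

    def test_empty_matrix_rejected(self):
        import pandas as pd

        from tvnet.dynamics import DegreeMatrix
        with pytest.raises(UsageError):
            render.render_stack(DegreeMatrix(pd.DataFrame()))


class TestRenderSeries:
    def test_frames_share_identical_node_coordinates(self, tmp_path, rng):
        snaps = [random_snapshot(rng, 10, k, time_label=str(k)) for k in (3, 8, 5)]
        series = series_of(*snaps)
        lay = tvlayout.assign_layout(tvlayout.cluster_order(series), 1)
        paths = render.render_series(series, lay, StyleConfig(), tmp_path)
        assert len(paths) == 3
        coords = []
        for p in paths:
            root = ET.parse(p).getroot()
            coords.append(sorted(
                (e.get("data-gene"), e.get("cx"), e.get("cy"))
                for e in root.iter() if e.get("class") == "node"))
        assert coords[0] == coords[1] == coords[2]

    def test_empty_series_yields_no_files(self, tmp_path):
        paths = render.render_series(series_of(), None, StyleConfig(), tmp_path)
        assert paths == []

    def test_chord_counts_per_frame_equal_activity_profile(self, tmp_path):
        from tvnet import synthgen

        series, _ = synthgen.generate(synthgen.periodic_cell_cycle_preset(11))
        lay = tvlayout.assign_layout(tvlayout.cluster_order(series), 3)
        paths = render.render_series(series, lay, StyleConfig(), tmp_path)
        profile = dynamics.activity_profile(series)  # oracle
        assert len(paths) == 24
        for p, (_t, count) in zip(paths, profile):
            root = ET.parse(p).getroot()
            n_edges = len([e for e in root.iter() if e.get("class") == "edge"])
            assert n_edges == count

    def test_filenames_embed_time_labels_in_order(self, tmp_path):
        series = series_of(snap("S1", [("a", "b", 1.0)]),
                           snap("T4", [("a", "b", 1.0)]))
        lay = tvlayout.assign_layout(tvlayout.cluster_order(series), 1)
        paths = render.render_series(series, lay, StyleConfig(), tmp_path)
        assert [p.name for p in paths] == ["net_000_S1.svg", "net_001_T4.svg"]
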
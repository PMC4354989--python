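"""Geometry, SVG emission, multi-viewer alignment."""

import dataclasses
import xml.etree.ElementTree as ET

import pytest
from hypothesis import given
from lxml import etree

from featuretrack.errors import AlignmentError, FeatureTrackError
from featuretrack.layout import has_overlaps, max_depth, merge_blocks
from featuretrack.model import (AnnotationRow, FeatureAnnotation, MarkerLine,
                                SummaryValue, ViewerSpec)
from featuretrack.render import (RenderConfig, StyleRule, layout_viewer,
                                 position_to_x, render_page, render_svg,
                                 render_viewer, score_shading_rule, shade)
from featuretrack.simulate import GeneratorParams, gen_viewer

from conftest import viewer_specs

CFG = RenderConfig()

OVERLAP_SPEC = ViewerSpec(
    sequence_length=30,
    rows=(AnnotationRow("r1", (FeatureAnnotation(2, 10),
                               FeatureAnnotation(8, 19))),))


def parse_svg(text: str):
    """Well-formedness gate: parsed by lxml, root must be an svg element."""
    root = etree.fromstring(text.encode())
    assert root.tag == "{http://www.w3.org/2000/svg}svg"
    return root


class TestPositionToX:
    def test_left_edge_identity(self):
        x_left, _ = position_to_x(1, 100, CFG)
        assert x_left == CFG.label_width

    def test_right_edge_identity(self):
        _, x_right = position_to_x(100, 100, CFG)
        assert x_right == CFG.label_width + CFG.plot_width

    def test_closed_form(self):
        cfg = dataclasses.replace(CFG, label_width=150.0, plot_width=600.0)
        x_left, _ = position_to_x(51, 100, cfg)
        assert x_left == pytest.approx(150 + 300.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(FeatureTrackError):
            position_to_x(0, 100, CFG)
        with pytest.raises(FeatureTrackError):
            position_to_x(101, 100, CFG)

    def test_strictly_increasing_and_width_exact(self):
        L = 73
        xs = [position_to_x(p, L, CFG) for p in range(1, L + 1)]
        assert all(a[0] < b[0] for a, b in zip(xs, xs[1:]))
        # block width of (s, e) is (e - s + 1) * plot_width / L
        s, e = 10, 30
        width = xs[e - 1][1] - xs[s - 1][0]
        assert width == pytest.approx((e - s + 1) * CFG.plot_width / L)


class TestLayout:
    def test_collapsed_overlap_gives_block_plus_indicator(self):
        layout = layout_viewer(OVERLAP_SPEC, CFG)
        assert len(layout.by_kind("block")) == 1
        assert len(layout.by_kind("indicator")) == 1
        block = layout.by_kind("block")[0]
        x0, _ = position_to_x(2, 30, CFG)
        _, x1 = position_to_x(19, 30, CFG)
        assert (block.x, block.x + block.width) == (pytest.approx(x0), pytest.approx(x1))

    def test_expanded_row_uses_subtracks(self):
        layout = layout_viewer(OVERLAP_SPEC, CFG, expanded={"r1"})
        anns = layout.by_kind("annotation")
        assert len(anns) == 2
        assert sorted(a.track_index for a in anns) == [0, 1]
        ys = sorted(a.y for a in anns)
        assert ys[1] - ys[0] == CFG.row_height + CFG.row_gap

    def test_expanding_row_without_overlaps_is_noop(self, caplog):
        spec = ViewerSpec(10, (AnnotationRow("r1", (FeatureAnnotation(1, 3),)),))
        layout = layout_viewer(spec, CFG, expanded={"r1"})
        assert len(layout.by_kind("block")) == 1
        assert not layout.by_kind("annotation")

    def test_summary_bar_proportional(self):
        spec = ViewerSpec(10, (AnnotationRow(
            "r1", (), summary=SummaryValue(value=0.5)),))
        bar = layout_viewer(spec, CFG).by_kind("summary")[0]
        assert bar.width == pytest.approx(CFG.summary_bar_width / 2)
        assert bar.x == CFG.label_width + CFG.plot_width + CFG.summary_gap

    def test_marker_spans_rows_at_position_midpoint(self):
        spec = ViewerSpec(
            10, (AnnotationRow("a", ()), AnnotationRow("b", ())),
            markers=(MarkerLine(position=5),))
        marker = layout_viewer(spec, CFG).by_kind("marker")[0]
        x0, x1 = position_to_x(5, 10, CFG)
        assert marker.x == pytest.approx((x0 + x1) / 2)
        rows_height = 2 * CFG.row_height + CFG.row_gap
        assert marker.height == pytest.approx(rows_height)

    @given(viewer_specs())
    def test_rectangles_stay_inside_plot(self, spec):
        layout = layout_viewer(spec, CFG)
        right = CFG.label_width + CFG.plot_width
        for e in layout.elements:
            if e.kind in ("block", "annotation"):
                assert e.x >= CFG.label_width - 1e-9
                assert e.x + e.width <= right + 1e-9
            assert e.x >= 0 and e.y >= 0
            assert e.x + e.width <= layout.width + 1e-9
            assert e.y + e.height <= layout.height + 1e-9

    @given(viewer_specs())
    def test_counts_match_layout_algebra(self, spec):
        """Collapsed rects == merged blocks; expanded rects == annotations;
        expanded sub-track count == max depth."""
        collapsed = layout_viewer(spec, CFG)
        n_blocks = sum(len(merge_blocks(r.annotations)) for r in spec.rows)
        assert len(collapsed.by_kind("block")) == n_blocks

        all_labels = {r.label for r in spec.rows}
        expanded = layout_viewer(spec, CFG, expanded=all_labels)
        overlapping = [r for r in spec.rows if has_overlaps(r.annotations)]
        n_expanded_rects = sum(len(r.annotations) for r in overlapping)
        anns = expanded.by_kind("annotation")
        assert len(anns) == n_expanded_rects
        if overlapping:
            assert 1 + max(a.track_index for a in anns) == \
                max(max_depth(r.annotations) for r in overlapping)


class TestSvg:
    def test_output_is_wellformed_svg(self):
        parse_svg(render_viewer(OVERLAP_SPEC))

    def test_empty_viewer_renders_frame_and_title(self):
        spec = ViewerSpec(10, (), title="empty")
        root = parse_svg(render_viewer(spec))
        assert b"empty" in etree.tostring(root)

    def test_tooltips_become_title_elements(self):
        spec = ViewerSpec(10, (AnnotationRow(
            "r", (FeatureAnnotation(2, 5, tooltip="my feature"),)),))
        root = parse_svg(render_viewer(spec))
        titles = root.findall(".//{http://www.w3.org/2000/svg}rect/"
                              "{http://www.w3.org/2000/svg}title")
        assert "my feature" in [t.text for t in titles]

    def test_urls_become_hyperlink_wrappers(self):
        spec = ViewerSpec(10, (AnnotationRow(
            "r", (FeatureAnnotation(2, 5, url="https://example.org/x"),)),))
        root = parse_svg(render_viewer(spec))
        links = root.findall(".//{http://www.w3.org/2000/svg}a")
        assert len(links) == 1
        href = links[0].get("{http://www.w3.org/1999/xlink}href")
        assert href == "https://example.org/x"

    def test_rerender_is_byte_identical(self):
        spec = gen_viewer(GeneratorParams(seed=7))
        assert render_viewer(spec) == render_viewer(spec)

    def test_every_rect_inside_viewbox(self):
        root = parse_svg(render_viewer(gen_viewer(GeneratorParams(seed=3))))
        _, _, vb_w, vb_h = (float(v) for v in root.get("viewBox").split())
        for rect in root.iter("{http://www.w3.org/2000/svg}rect"):
            x, y = float(rect.get("x")), float(rect.get("y"))
            w, h = float(rect.get("width")), float(rect.get("height"))
            assert 0 <= x and x + w <= vb_w + 1e-6
            assert 0 <= y and y + h <= vb_h + 1e-6


class TestPage:
    def test_equal_positions_share_x_across_viewers(self):
        a = ViewerSpec(40, (AnnotationRow("a", (FeatureAnnotation(10, 20),)),))
        b = ViewerSpec(40, (AnnotationRow("b", (FeatureAnnotation(10, 20),)),))
        svg = render_page([a, b], CFG, markers=(MarkerLine(position=25),))
        root = parse_svg(svg)
        ns = "{http://www.w3.org/2000/svg}"
        lines = root.findall(f".//{ns}line")
        assert len(lines) == 2
        assert abs(float(lines[0].get("x1")) - float(lines[1].get("x1"))) < 1e-6
        rects = [r for r in root.iter(f"{ns}rect")
                 if r.get("fill") not in ("white", "none")]
        xs = sorted({float(r.get("x")) for r in rects if float(r.get("width")) > 0})
        # the two annotation blocks for positions 10-20 share their x
        assert any(abs(x - position_to_x(10, 40, CFG)[0]) < 1e-6 for x in xs)

    def test_mismatched_lengths_raise_alignment_error(self):
        with pytest.raises(AlignmentError) as err:
            render_page([ViewerSpec(100, ()), ViewerSpec(120, ())])
        assert err.value.lengths == [100, 120]

    def test_singleton_page_equals_single_viewer(self):
        spec = gen_viewer(GeneratorParams(seed=5))
        assert render_page([spec]) == render_viewer(spec)


class TestStyle:
    def test_shade_interpolates_to_black(self):
        assert shade("#ff0000", 0.0) == "#000000"
        assert shade("#ff0000", 1.0) == "#ff0000"
        assert shade("#ff0000", 0.5) == "#800000"

    def test_score_shading_dark_to_bright(self):
        anns = (FeatureAnnotation(1, 2, score=0.0),
                FeatureAnnotation(3, 4, score=1.0))
        rule = score_shading_rule(anns, base_color="#ff0000")
        assert rule.color_of(anns[0]) == "#000000"
        assert rule.color_of(anns[1]) == "#ff0000"

    def test_style_rule_overrides_record_color(self):
        spec = ViewerSpec(10, (AnnotationRow(
            "r", (FeatureAnnotation(2, 5, color="blue"),)),))
        style = StyleRule(color_of=lambda a: "#123456")
        layout = layout_viewer(spec, CFG, style=style)
        assert layout.by_kind("block")[0].color == "#123456"
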
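"""Geometry and SVG emission for annotation viewers.

A viewer maps sequence position ``p`` of a length-``L`` sequence onto the
horizontal pixel band

    x_left(p)  = label_width + (p - 1) * plot_width / L
    x_right(p) = label_width + p * plot_width / L

so position 1 starts at the plot's left edge and position L ends at its right
edge; a block for annotation (s, e) spans ``[x_left(s), x_right(e)]``.  All
viewers on a page share ``label_width`` and ``plot_width``, so equal
positions land at equal x and can be compared across viewers.

Layout (:func:`layout_viewer`) and emission (:func:`render_svg`) are
separate: layout resolves geometry plus per-record style (color, tooltip,
link) into flat :class:`LayoutElement` records; emission turns those into a
standalone SVG 1.1 document.  Interactivity is static — tooltips become SVG
``<title>`` children (shown on hover by every major viewer) and click-through
URLs become SVG hyperlink wrappers.  Output is deterministic: the same spec,
config and style always produce byte-identical SVG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence
from xml.etree import ElementTree as ET

from .errors import AlignmentError, FeatureTrackError, ValidationError
from .layout import assign_tracks, has_overlaps, merge_blocks
from .model import (AnnotationRow, FeatureAnnotation, MarkerLine, SummaryValue,
                    ViewerSpec, validate_viewer)

logger = logging.getLogger(__name__)

__all__ = [
    "RenderConfig", "StyleRule", "LayoutElement", "Layout",
    "position_to_x", "layout_viewer", "render_svg", "render_page",
    "render_viewer", "shade", "score_shading_rule",
]


@dataclass(frozen=True)
class RenderConfig:
    """Pixel-level display parameters (row heights, widths, colors, fonts)."""

    row_height: float = 20.0
    row_gap: float = 4.0
    label_width: float = 150.0
    plot_width: float = 600.0
    summary_bar_width: float = 80.0
    summary_gap: float = 10.0
    font_size: float = 12.0
    border_color: str = "gray"
    background: str = "white"
    marker_color: str = "green"
    indicator_size: float = 10.0
    padding: float = 10.0
    viewer_gap: float = 16.0
    block_color: str = "#4878cf"  # fallback when neither record nor row set one

    def __post_init__(self):
        for name in ("row_height", "row_gap", "label_width", "plot_width",
                     "summary_bar_width", "summary_gap", "font_size",
                     "indicator_size"):
            if getattr(self, name) <= 0 and name not in ("row_gap",):
                raise ValueError(f"RenderConfig.{name} must be > 0")


@dataclass(frozen=True)
class StyleRule:
    """Pluggable, pure mapping from data records to display attributes.

    Each function receives the annotation / summary / marker record and
    returns a CSS color, tooltip text, or link target; ``None`` falls back to
    the record's own field, then the row default, then the config default.
    """

    color_of: Callable[[FeatureAnnotation], str | None] = lambda a: a.color
    tooltip_of: Callable[[FeatureAnnotation], str | None] = lambda a: a.tooltip
    url_of: Callable[[FeatureAnnotation], str | None] = lambda a: a.url
    summary_color_of: Callable[[SummaryValue], str | None] = lambda s: s.color
    summary_tooltip_of: Callable[[SummaryValue], str | None] = lambda s: s.tooltip
    summary_url_of: Callable[[SummaryValue], str | None] = lambda s: s.url
    marker_color_of: Callable[[MarkerLine], str | None] = lambda m: m.color


DEFAULT_STYLE = StyleRule()


def _parse_css_color(color: str) -> tuple[int, int, int] | None:
    c = color.strip().lstrip("#")
    if len(c) == 3 and all(ch in "0123456789abcdefABCDEF" for ch in c):
        c = "".join(ch * 2 for ch in c)
    if len(c) == 6 and all(ch in "0123456789abcdefABCDEF" for ch in c):
        return int(c[0:2], 16), int(c[2:4], 16), int(c[4:6], 16)
    return None


def shade(base_color: str, t: float) -> str:
    """Linear interpolation from black (t=0) to ``base_color`` (t=1)."""
    t = min(1.0, max(0.0, t))
    rgb = _parse_css_color(base_color)
    if rgb is None:  # named colors cannot be interpolated; return as-is
        return base_color
    return "#{:02x}{:02x}{:02x}".format(*(round(v * t) for v in rgb))


def score_shading_rule(annotations: Iterable[FeatureAnnotation],
                       base_color: str = "#d62728") -> StyleRule:
    """A style whose block color encodes the annotation score.

    Scores are rescaled over the observed range and mapped onto a black →
    ``base_color`` ramp (dark = low score, bright = high).  Annotations
    without a score keep the base color.
    """
    scores = [a.score for a in annotations if a.score is not None]
    lo, hi = (min(scores), max(scores)) if scores else (0.0, 1.0)
    span = hi - lo

    def color_of(a: FeatureAnnotation) -> str:
        if a.score is None:
            return base_color
        t = 1.0 if span == 0 else (a.score - lo) / span
        return shade(base_color, t)

    return StyleRule(color_of=color_of)


def position_to_x(pos: int, sequence_length: int,
                  config: RenderConfig) -> tuple[float, float]:
    """Pixel band ``(x_left, x_right)`` of one sequence position."""
    if not 1 <= pos <= sequence_length:
        raise FeatureTrackError(
            f"position {pos} outside [1, {sequence_length}]")
    unit = config.plot_width / sequence_length
    return (config.label_width + (pos - 1) * unit,
            config.label_width + pos * unit)


@dataclass(frozen=True)
class LayoutElement:
    """One drawable item: a rectangle, marker line, label or indicator.

    ``kind`` is one of block, annotation, summary, marker, indicator, label,
    title, frame.  Marker elements use ``x`` as the line's x coordinate and
    ``width`` 0.  ``track_index`` is the sub-track for expanded annotations.
    """

    kind: str
    x: float
    y: float
    width: float
    height: float
    color: str | None = None
    text: str | None = None
    tooltip: str | None = None
    url: str | None = None
    track_index: int = 0
    source: object = None


@dataclass(frozen=True)
class Layout:
    width: float
    height: float
    elements: tuple[LayoutElement, ...]
    config: RenderConfig

    def by_kind(self, kind: str) -> list[LayoutElement]:
        return [e for e in self.elements if e.kind == kind]


def _resolve(style_value, record_value, fallback):
    return style_value if style_value is not None else (
        record_value if record_value is not None else fallback)


def _row_band_height(row: AnnotationRow, expanded: bool,
                     config: RenderConfig) -> tuple[float, int]:
    """(pixel height, n sub-tracks) of one row's band."""
    if expanded:
        n = assign_tracks(row.annotations).n_tracks or 1
    else:
        n = 1
    return n * config.row_height + (n - 1) * config.row_gap, n


def layout_viewer(spec: ViewerSpec, config: RenderConfig = RenderConfig(),
                  expanded: set[str] | None = None,
                  style: StyleRule = DEFAULT_STYLE,
                  y_offset: float = 0.0) -> Layout:
    """Compute all drawable elements of one viewer.

    ``expanded`` names the rows (by label) to show in expanded mode; rows
    without overlapping annotations ignore the request (logged), since their
    collapsed blocks already show every annotation.  Collapsed rows draw one
    rectangle per merged block plus an expand indicator when overlaps exist;
    expanded rows draw one rectangle per annotation, offset vertically by its
    sub-track.  A summary bar, proportional to the summary value, sits right
    of the plot; marker lines span the full row stack.
    """
    violations = validate_viewer(spec)
    if violations:
        raise ValidationError(violations)
    expanded = expanded or set()
    L = spec.sequence_length
    els: list[LayoutElement] = []

    y = y_offset + config.padding
    if spec.title:
        els.append(LayoutElement("title", config.label_width, y + config.font_size,
                                 0, config.font_size, text=spec.title))
        y += config.font_size + config.row_gap
    rows_top = y

    for row in spec.rows:
        overlapping = has_overlaps(row.annotations)
        expand = row.label in expanded
        if expand and not overlapping:
            logger.info("row %r has no overlapping annotations; "
                        "expand request is a no-op", row.label)
            expand = False
        band_h, _ = _row_band_height(row, expand, config)

        els.append(LayoutElement(
            "label", config.padding, y + config.row_height / 2 + config.font_size / 3,
            0, config.font_size, text=row.label, source=row))
        if overlapping:
            s = config.indicator_size
            els.append(LayoutElement(
                "indicator", config.label_width - s - 4,
                y + (config.row_height - s) / 2, s, s,
                color=config.border_color,
                tooltip=f"{len(row.annotations)} annotations, overlapping",
                source=row))

        if expand:
            assignment = assign_tracks(row.annotations)
            for a, t in zip(row.annotations, assignment.track_index):
                x0, _ = position_to_x(a.start, L, config)
                _, x1 = position_to_x(a.end, L, config)
                els.append(LayoutElement(
                    "annotation", x0,
                    y + t * (config.row_height + config.row_gap),
                    x1 - x0, config.row_height,
                    color=_resolve(style.color_of(a), row.default_color,
                                   config.block_color),
                    tooltip=_resolve(style.tooltip_of(a), None,
                                     f"{a.label or 'annotation'} {a.start}–{a.end}"),
                    url=style.url_of(a), track_index=t, source=a))
        else:
            for block in merge_blocks(row.annotations):
                first = row.annotations[block.members[0]]
                x0, _ = position_to_x(block.start, L, config)
                _, x1 = position_to_x(block.end, L, config)
                tooltip = (style.tooltip_of(first) if len(block.members) == 1
                           else None)
                if tooltip is None:
                    tooltip = (f"{len(block.members)} annotations "
                               f"{block.start}–{block.end}"
                               if len(block.members) > 1 else
                               f"{first.label or 'annotation'} "
                               f"{first.start}–{first.end}")
                els.append(LayoutElement(
                    "block", x0, y, x1 - x0, config.row_height,
                    color=_resolve(style.color_of(first), row.default_color,
                                   config.block_color),
                    tooltip=tooltip,
                    url=style.url_of(first) if len(block.members) == 1 else None,
                    source=block))

        if row.summary is not None:
            s = row.summary
            els.append(LayoutElement(
                "summary",
                config.label_width + config.plot_width + config.summary_gap,
                y, s.value * config.summary_bar_width, config.row_height,
                color=_resolve(style.summary_color_of(s), row.default_color,
                               config.border_color),
                tooltip=_resolve(style.summary_tooltip_of(s), None,
                                 s.label or f"summary {s.value:g}"),
                url=style.summary_url_of(s), source=s))

        y += band_h + config.row_gap

    rows_bottom = y - config.row_gap if spec.rows else rows_top
    # an empty viewer still shows a one-row-high frame
    rows_bottom = max(rows_bottom, rows_top + config.row_height)
    for m in spec.markers:
        x0, x1 = position_to_x(m.position, L, config)
        els.append(LayoutElement(
            "marker", (x0 + x1) / 2, rows_top, 0.0, rows_bottom - rows_top,
            color=_resolve(style.marker_color_of(m), None, config.marker_color),
            tooltip=m.label, source=m))

    width = (config.label_width + config.plot_width + config.summary_gap
             + config.summary_bar_width + config.padding)
    height = rows_bottom + config.padding - y_offset
    # plot frame behind the rows
    els.insert(0, LayoutElement(
        "frame", config.label_width, rows_top, config.plot_width,
        rows_bottom - rows_top))
    return Layout(width, height + y_offset, tuple(els), config)


def _fmt(v: float) -> str:
    s = f"{v:.3f}".rstrip("0").rstrip(".")
    return s if s != "-0" else "0"


def _rect_svg(parent: ET.Element, e: LayoutElement, stroke: str | None = None):
    holder = parent
    if e.url:
        holder = ET.SubElement(parent, "a", {"xlink:href": e.url})
    attrs = {"x": _fmt(e.x), "y": _fmt(e.y),
             "width": _fmt(e.width), "height": _fmt(e.height),
             "fill": e.color or "none"}
    if stroke:
        attrs["stroke"] = stroke
    rect = ET.SubElement(holder, "rect", attrs)
    if e.tooltip:
        ET.SubElement(rect, "title").text = e.tooltip
    return rect


def render_svg(layout: Layout) -> str:
    """Emit one layout as a standalone SVG 1.1 document (UTF-8 text)."""
    return _emit([layout])


def _emit(layouts: Sequence[Layout]) -> str:
    config = layouts[0].config
    width = max(l.width for l in layouts)
    height = layouts[-1].height
    svg = ET.Element("svg", {
        "xmlns": "http://www.w3.org/2000/svg",
        "xmlns:xlink": "http://www.w3.org/1999/xlink",
        "version": "1.1",
        "width": _fmt(width), "height": _fmt(height),
        "viewBox": f"0 0 {_fmt(width)} {_fmt(height)}",
    })
    ET.SubElement(svg, "rect", {"x": "0", "y": "0", "width": _fmt(width),
                                "height": _fmt(height),
                                "fill": config.background})
    for layout in layouts:
        g = ET.SubElement(svg, "g")
        for e in layout.elements:
            if e.kind == "frame":
                ET.SubElement(g, "rect", {
                    "x": _fmt(e.x), "y": _fmt(e.y), "width": _fmt(e.width),
                    "height": _fmt(e.height), "fill": "none",
                    "stroke": layout.config.border_color})
            elif e.kind in ("block", "annotation", "summary"):
                _rect_svg(g, e)
            elif e.kind == "indicator":
                rect = _rect_svg(g, e, stroke=layout.config.border_color)
                rect.set("fill", "white")
                cx, cy, s = e.x + e.width / 2, e.y + e.height / 2, e.width
                ET.SubElement(g, "path", {
                    "d": (f"M {_fmt(e.x + 2)} {_fmt(cy)} H {_fmt(e.x + s - 2)} "
                          f"M {_fmt(cx)} {_fmt(e.y + 2)} V {_fmt(e.y + s - 2)}"),
                    "stroke": "black", "fill": "none"})
            elif e.kind == "marker":
                line = ET.SubElement(g, "line", {
                    "x1": _fmt(e.x), "y1": _fmt(e.y),
                    "x2": _fmt(e.x), "y2": _fmt(e.y + e.height),
                    "stroke": e.color or layout.config.marker_color})
                if e.tooltip:
                    ET.SubElement(line, "title").text = e.tooltip
            elif e.kind in ("label", "title"):
                text = ET.SubElement(g, "text", {
                    "x": _fmt(e.x), "y": _fmt(e.y),
                    "font-size": _fmt(layout.config.font_size),
                    "font-family": "sans-serif"})
                text.text = e.text or ""
    body = ET.tostring(svg, encoding="unicode")
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + body + "\n"


def render_viewer(spec: ViewerSpec, config: RenderConfig = RenderConfig(),
                  expanded: set[str] | None = None,
                  style: StyleRule = DEFAULT_STYLE) -> str:
    """Layout + emit one viewer in a single call."""
    return render_svg(layout_viewer(spec, config, expanded, style))


def render_page(specs: Sequence[ViewerSpec],
                config: RenderConfig = RenderConfig(),
                expanded: set[str] | None = None,
                style: StyleRule = DEFAULT_STYLE,
                markers: Sequence[MarkerLine] = ()) -> str:
    """Stack several viewers of one sequence into a single aligned SVG.

    All viewers must share one sequence length; since they also share the
    config's ``label_width`` and ``plot_width``, equal sequence positions get
    equal x coordinates in every viewer.  Page-level ``markers`` are drawn at
    the same x in each viewer.
    """
    lengths = {s.sequence_length for s in specs}
    if len(lengths) > 1:
        raise AlignmentError(sorted(s.sequence_length for s in specs))
    layouts = []
    y = 0.0
    for i, spec in enumerate(specs):
        if markers:
            merged = spec.markers + tuple(m for m in markers
                                          if m.position not in
                                          {sm.position for sm in spec.markers})
            spec = ViewerSpec(spec.sequence_length, spec.rows, spec.title, merged)
        layout = layout_viewer(spec, config, expanded, style, y_offset=y)
        layouts.append(layout)
        y = layout.height + (config.viewer_gap if i < len(specs) - 1 else 0.0)
    return _emit(layouts)
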
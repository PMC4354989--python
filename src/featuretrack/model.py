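"""Domain types for sequence feature annotation viewers.

The coordinate model throughout the package is 1-based and inclusive on both
ends: an annotation ``(2, 10)`` covers positions 2..10 of the sequence, with
position 1 drawn at the left edge of a viewer and the final position at the
right edge.  Only the sequence length is stored, never residue letters.

A :class:`ViewerSpec` is the unit rendered as one viewer: a single sequence
plus one or more labeled :class:`AnnotationRow` objects and optional vertical
:class:`MarkerLine` positions.  The generic JSON dialect read and written here
(:func:`read_generic_json` / :func:`write_generic_json`) carries every
capability of the viewer: tooltips, per-annotation URLs, scores for shading,
row-level coloring, row summary bars and marker lines.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

from .errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureAnnotation",
    "SummaryValue",
    "AnnotationRow",
    "MarkerLine",
    "ViewerSpec",
    "Violation",
    "validate_viewer",
    "normalize_row",
    "normalize_viewer",
    "read_generic_json",
    "write_generic_json",
]


@dataclass(frozen=True)
class FeatureAnnotation:
    """One annotated region: inclusive ``start``..``end`` plus display metadata.

    ``score`` is an unconstrained real; mapping it to a shade is a style
    concern, not a model one.  ``color`` is any CSS color string.
    """

    start: int
    end: int
    label: str = ""
    score: float | None = None
    color: str | None = None
    tooltip: str | None = None
    url: str | None = None


@dataclass(frozen=True)
class SummaryValue:
    """Row-level summary statistic; ``value`` is the fraction of the full
    summary-bar width, so it must lie in [0, 1]."""

    value: float
    label: str = ""
    color: str | None = None
    tooltip: str | None = None
    url: str | None = None


@dataclass(frozen=True)
class MarkerLine:
    """A vertical line of interest at one sequence position (e.g. a trypsin
    cut site), drawn across all rows."""

    position: int
    color: str | None = None
    label: str | None = None


@dataclass(frozen=True)
class AnnotationRow:
    label: str
    annotations: tuple[FeatureAnnotation, ...] = ()
    summary: SummaryValue | None = None
    default_color: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "annotations", tuple(self.annotations))


@dataclass(frozen=True)
class ViewerSpec:
    """One sequence (length + title) with its annotation rows and markers."""

    sequence_length: int
    rows: tuple[AnnotationRow, ...] = ()
    title: str = ""
    markers: tuple[MarkerLine, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "rows", tuple(self.rows))
        object.__setattr__(self, "markers", tuple(self.markers))


@dataclass(frozen=True)
class Violation:
    """One violated invariant; ``row`` / ``annotation`` / ``marker`` locate the
    offending record (None where not applicable)."""

    rule: str
    message: str
    row: int | None = None
    annotation: int | None = None
    marker: int | None = None

    def __str__(self) -> str:
        loc = []
        if self.row is not None:
            loc.append(f"row {self.row}")
        if self.annotation is not None:
            loc.append(f"annotation {self.annotation}")
        if self.marker is not None:
            loc.append(f"marker {self.marker}")
        where = " ".join(loc) or "viewer"
        return f"{where}: {self.message} [{self.rule}]"


def validate_viewer(spec: ViewerSpec) -> list[Violation]:
    """Check every coordinate invariant; return one record per violation.

    Violations are data, not exceptions: an empty list means the spec is
    valid.  The input is never mutated.
    """
    out: list[Violation] = []
    if spec.sequence_length < 1:
        out.append(Violation("sequence_length_ge_1",
                             f"sequence_length must be >= 1, got {spec.sequence_length}"))
    for i, row in enumerate(spec.rows):
        for j, a in enumerate(row.annotations):
            if a.start < 1:
                out.append(Violation("start_ge_1",
                                     f"start must be >= 1, got {a.start}", i, j))
            if a.start > a.end:
                out.append(Violation("start_le_end",
                                     f"start {a.start} > end {a.end}", i, j))
            if a.end > spec.sequence_length:
                out.append(Violation(
                    "end_le_sequence_length",
                    f"end {a.end} > sequence length {spec.sequence_length}", i, j))
        if row.summary is not None and not (0.0 <= row.summary.value <= 1.0):
            out.append(Violation("summary_value_in_unit_interval",
                                 f"summary value {row.summary.value} outside [0, 1]", i))
    for k, m in enumerate(spec.markers):
        if not (1 <= m.position <= spec.sequence_length):
            out.append(Violation(
                "marker_in_range",
                f"marker position {m.position} outside [1, {spec.sequence_length}]",
                marker=k))
    return out


def normalize_row(row: AnnotationRow) -> AnnotationRow:
    """Stably sort annotations by (start, end, original index); idempotent."""
    order = sorted(range(len(row.annotations)),
                   key=lambda i: (row.annotations[i].start, row.annotations[i].end, i))
    return replace(row, annotations=tuple(row.annotations[i] for i in order))


def normalize_viewer(spec: ViewerSpec) -> ViewerSpec:
    return replace(spec, rows=tuple(normalize_row(r) for r in spec.rows))


# --- generic JSON dialect -------------------------------------------------
#
# { "title": str?, "sequenceLength": int,
#   "rows": [ { "label": str, "defaultColor": str?,
#               "summary": {"value": num, "label": str?, "color": str?,
#                           "tooltip": str?, "url": str?}?,
#               "annotations": [ {"start": int, "end": int, "label": str?,
#                                 "score": num?, "color": str?,
#                                 "tooltip": str?, "url": str?} ] } ],
#   "markers": [ {"position": int, "color": str?, "label": str?} ]? }

_ANNOTATION_KEYS = {"start", "end", "label", "score", "color", "tooltip", "url"}
_SUMMARY_KEYS = {"value", "label", "color", "tooltip", "url"}
_ROW_KEYS = {"label", "defaultColor", "summary", "annotations"}
_MARKER_KEYS = {"position", "color", "label"}
_TOP_KEYS = {"title", "sequenceLength", "rows", "markers"}


def _require(obj: dict, key: str, path: str):
    if key not in obj:
        raise SchemaError(f"missing required key '{key}'", path)
    return obj[key]


def _expect(value, types, what: str, path: str):
    # bool is an int subclass but never a valid position/score
    if isinstance(value, bool) or not isinstance(value, types):
        raise SchemaError(f"{what} must be {types if isinstance(types, type) else 'one of the expected types'}, "
                          f"got {type(value).__name__}", path)
    return value


def _warn_unknown(obj: dict, known: set, path: str) -> None:
    for key in obj.keys() - known:
        logger.warning("ignoring unknown key %r at %s", key, path)


def _opt_str(obj: dict, key: str, path: str) -> str | None:
    if key not in obj or obj[key] is None:
        return None
    return _expect(obj[key], str, key, f"{path}.{key}")


def read_generic_json(text: str) -> ViewerSpec:
    """Parse the generic annotation JSON dialect into a validated, normalized
    :class:`ViewerSpec`.

    Unknown keys are ignored with a logged warning so documents written for
    richer future dialects still load.  Raises :class:`ParseError` on
    malformed JSON, :class:`SchemaError` on missing/ill-typed required keys
    (with a JSON path), and :class:`ValidationError` when coordinates violate
    the viewer invariants.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed JSON: {exc.msg}", line=exc.lineno) from exc
    if not isinstance(doc, dict):
        raise SchemaError("top-level value must be an object", "$")
    _warn_unknown(doc, _TOP_KEYS, "$")

    length = _expect(_require(doc, "sequenceLength", "$"), int,
                     "sequenceLength", "$.sequenceLength")
    title = _opt_str(doc, "title", "$") or ""

    rows_raw = _expect(_require(doc, "rows", "$"), list, "rows", "$.rows")
    rows = []
    for i, row_raw in enumerate(rows_raw):
        rpath = f"$.rows[{i}]"
        _expect(row_raw, dict, "row", rpath)
        _warn_unknown(row_raw, _ROW_KEYS, rpath)
        label = _expect(_require(row_raw, "label", rpath), str, "label", f"{rpath}.label")
        anns_raw = _expect(_require(row_raw, "annotations", rpath), list,
                           "annotations", f"{rpath}.annotations")
        anns = []
        for j, a in enumerate(anns_raw):
            apath = f"{rpath}.annotations[{j}]"
            _expect(a, dict, "annotation", apath)
            _warn_unknown(a, _ANNOTATION_KEYS, apath)
            score = a.get("score")
            if score is not None:
                _expect(score, (int, float), "score", f"{apath}.score")
            anns.append(FeatureAnnotation(
                start=_expect(_require(a, "start", apath), int, "start", f"{apath}.start"),
                end=_expect(_require(a, "end", apath), int, "end", f"{apath}.end"),
                label=_opt_str(a, "label", apath) or "",
                score=score,
                color=_opt_str(a, "color", apath),
                tooltip=_opt_str(a, "tooltip", apath),
                url=_opt_str(a, "url", apath),
            ))
        summary = None
        if row_raw.get("summary") is not None:
            s = row_raw["summary"]
            spath = f"{rpath}.summary"
            _expect(s, dict, "summary", spath)
            _warn_unknown(s, _SUMMARY_KEYS, spath)
            summary = SummaryValue(
                value=_expect(_require(s, "value", spath), (int, float),
                              "value", f"{spath}.value"),
                label=_opt_str(s, "label", spath) or "",
                color=_opt_str(s, "color", spath),
                tooltip=_opt_str(s, "tooltip", spath),
                url=_opt_str(s, "url", spath),
            )
        rows.append(AnnotationRow(label=label, annotations=tuple(anns),
                                  summary=summary,
                                  default_color=_opt_str(row_raw, "defaultColor", rpath)))

    markers = []
    if doc.get("markers") is not None:
        for k, m in enumerate(_expect(doc["markers"], list, "markers", "$.markers")):
            mpath = f"$.markers[{k}]"
            _expect(m, dict, "marker", mpath)
            _warn_unknown(m, _MARKER_KEYS, mpath)
            markers.append(MarkerLine(
                position=_expect(_require(m, "position", mpath), int,
                                 "position", f"{mpath}.position"),
                color=_opt_str(m, "color", mpath),
                label=_opt_str(m, "label", mpath),
            ))

    spec = ViewerSpec(sequence_length=length, rows=tuple(rows),
                      title=title, markers=tuple(markers))
    violations = validate_viewer(spec)
    if violations:
        raise ValidationError(violations)
    return normalize_viewer(spec)


def _drop_none(d: dict) -> dict:
    return {k: v for k, v in d.items() if v not in (None, "")}


def write_generic_json(spec: ViewerSpec) -> str:
    """Serialize a valid spec to the dialect; absent optionals are omitted and
    key order is fixed, so two writes of one spec are byte-identical."""
    violations = validate_viewer(spec)
    if violations:
        raise ValidationError(violations)
    spec = normalize_viewer(spec)

    doc: dict = {}
    if spec.title:
        doc["title"] = spec.title
    doc["sequenceLength"] = spec.sequence_length
    doc["rows"] = []
    for row in spec.rows:
        r: dict = {"label": row.label}
        if row.default_color is not None:
            r["defaultColor"] = row.default_color
        if row.summary is not None:
            s = row.summary
            r["summary"] = _drop_none({
                "value": s.value, "label": s.label, "color": s.color,
                "tooltip": s.tooltip, "url": s.url,
            })
        r["annotations"] = [
            _drop_none({"start": a.start, "end": a.end, "label": a.label,
                        "score": a.score, "color": a.color,
                        "tooltip": a.tooltip, "url": a.url})
            for a in row.annotations
        ]
        doc["rows"].append(r)
    if spec.markers:
        doc["markers"] = [
            _drop_none({"position": m.position, "color": m.color, "label": m.label})
            for m in spec.markers
        ]
    return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"
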
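"""Parsers for per-residue prediction outputs and their conversion to rows.

Three vertical per-residue formats are supported, each produced by a widely
used protein prediction program that must be run in advance:

``.ss2``
    psipred secondary structure (VFORMAT): optional ``#`` header lines and
    blank lines, then ``pos aa state coil_score helix_score strand_score``
    with state in {C, H, E}.
``.pc2``
    Paircoil2 coiled-coil predictions: ``#`` header lines, then at minimum
    ``pos aa register p_score`` (heptad register a-g; extra columns ignored).
    Low p-score means *stronger* coiled-coil evidence; residues are kept when
    p-score <= threshold (customary cutoff 0.025).
``.diso``
    DISOPRED disorder predictions: ``#`` header lines, then
    ``pos aa state confidence`` with state ``*`` (disordered) or ``.``.

All parsers are whitespace-tolerant, require positions to run contiguously
1..N, and report errors with the offending line number.  Conversion to an
:class:`~featuretrack.model.AnnotationRow` is run-length encoding: one
annotation per maximal run of residues in an annotated state, scored by the
mean per-residue score (ss2, diso) or the minimum p-score (pc2 — the run's
best evidence).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from .errors import ParameterError, ParseError
from .layout import Interval
from .model import AnnotationRow, FeatureAnnotation, ViewerSpec

__all__ = [
    "ResidueStateRecord",
    "runs_of",
    "read_ss2", "ss2_to_row",
    "read_pc2", "pc2_to_row",
    "read_diso", "diso_to_row",
    "convert", "FORMATS",
    "HELIX_COLOR", "STRAND_COLOR", "COILED_COIL_COLOR", "DISORDER_COLOR",
    "DEFAULT_P_THRESHOLD",
]

# Fig-2-style palette: green helices, blue strands, cyan coiled coils,
# black disordered regions.
HELIX_COLOR = "#2ca05a"
STRAND_COLOR = "#3465c0"
COILED_COIL_COLOR = "#00b5c8"
DISORDER_COLOR = "#000000"

DEFAULT_P_THRESHOLD = 0.025


@dataclass(frozen=True)
class ResidueStateRecord:
    """One residue of a vertical prediction file.

    ``score`` is format-specific: a mapping of per-state scores for ss2
    (keys C/H/E), the p-score for pc2, the confidence for diso.
    """

    position: int
    residue: str
    state: str
    score: float | Mapping[str, float]


def _data_lines(text: str):
    """Yield (line_number, fields) for non-blank, non-comment lines."""
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        yield lineno, line.split()


def _check_contiguous(records: Sequence[ResidueStateRecord], linenos: Sequence[int]):
    for i, rec in enumerate(records):
        if rec.position != i + 1:
            raise ParseError(
                f"positions must run contiguously from 1; expected {i + 1}, "
                f"got {rec.position}", line=linenos[i])


def _float(field: str, what: str, lineno: int) -> float:
    try:
        return float(field)
    except ValueError:
        raise ParseError(f"{what} is not a number: {field!r}", line=lineno) from None


def _int(field: str, what: str, lineno: int) -> int:
    try:
        return int(field)
    except ValueError:
        raise ParseError(f"{what} is not an integer: {field!r}", line=lineno) from None


def read_ss2(text: str) -> list[ResidueStateRecord]:
    records, linenos = [], []
    for lineno, fields in _data_lines(text):
        if len(fields) != 6:
            raise ParseError(f"expected 6 columns (pos aa state c h e), "
                             f"got {len(fields)}", line=lineno)
        pos, aa, state = _int(fields[0], "position", lineno), fields[1], fields[2]
        if state not in ("C", "H", "E"):
            raise ParseError(f"state must be C, H or E, got {state!r}", line=lineno)
        scores = {
            "C": _float(fields[3], "coil score", lineno),
            "H": _float(fields[4], "helix score", lineno),
            "E": _float(fields[5], "strand score", lineno),
        }
        records.append(ResidueStateRecord(pos, aa, state, scores))
        linenos.append(lineno)
    if not records:
        raise ParseError("no residue records found (empty file?)")
    _check_contiguous(records, linenos)
    return records


def read_pc2(text: str) -> list[ResidueStateRecord]:
    records, linenos = [], []
    for lineno, fields in _data_lines(text):
        if len(fields) < 4:
            raise ParseError(f"expected at least 4 columns (pos aa register "
                             f"p_score), got {len(fields)}", line=lineno)
        pos = _int(fields[0], "position", lineno)
        register = fields[2]
        if register not in "abcdefg" or len(register) != 1:
            raise ParseError(f"heptad register must be a-g, got {register!r}",
                             line=lineno)
        p = _float(fields[3], "p-score", lineno)
        records.append(ResidueStateRecord(pos, fields[1], register, p))
        linenos.append(lineno)
    if not records:
        raise ParseError("no residue records found (empty file?)")
    _check_contiguous(records, linenos)
    return records


def read_diso(text: str) -> list[ResidueStateRecord]:
    records, linenos = [], []
    for lineno, fields in _data_lines(text):
        if len(fields) != 4:
            raise ParseError(f"expected 4 columns (pos aa state confidence), "
                             f"got {len(fields)}", line=lineno)
        pos, aa, state = _int(fields[0], "position", lineno), fields[1], fields[2]
        if state not in ("*", "."):
            raise ParseError(f"state must be '*' or '.', got {state!r}", line=lineno)
        conf = _float(fields[3], "confidence", lineno)
        records.append(ResidueStateRecord(pos, aa, state, conf))
        linenos.append(lineno)
    if not records:
        raise ParseError("no residue records found (empty file?)")
    _check_contiguous(records, linenos)
    return records


def runs_of(
    records: Sequence[ResidueStateRecord],
    keep: Callable[[ResidueStateRecord], bool],
    group_by: Callable[[ResidueStateRecord], object] | None = None,
) -> list[tuple[Interval, list[ResidueStateRecord]]]:
    """Maximal runs of consecutive kept residues, in order.

    With ``group_by``, a run additionally breaks whenever the group key
    changes (e.g. helix vs strand runs within one pass).
    """
    runs: list[tuple[Interval, list[ResidueStateRecord]]] = []
    current: list[ResidueStateRecord] = []

    def flush():
        if current:
            runs.append((Interval(current[0].position, current[-1].position),
                         list(current)))
            current.clear()

    prev_key = object()
    for rec in records:
        if keep(rec):
            key = group_by(rec) if group_by is not None else None
            if current and key != prev_key:
                flush()
            current.append(rec)
            prev_key = key
        else:
            flush()
    flush()
    return runs


def _mean(values: Iterable[float]) -> float:
    values = list(values)
    return sum(values) / len(values)


def ss2_to_row(records: Sequence[ResidueStateRecord],
               label: str = "secondary structure") -> AnnotationRow:
    """Helix and strand runs become annotations; coil produces none.

    Each annotation's score is the mean of its own state's per-residue score
    over the run; helices and strands get distinct default colors.
    """
    names = {"H": "helix", "E": "strand"}
    colors = {"H": HELIX_COLOR, "E": STRAND_COLOR}
    anns = []
    for iv, run in runs_of(records, lambda r: r.state in ("H", "E"),
                           group_by=lambda r: r.state):
        state = run[0].state
        anns.append(FeatureAnnotation(
            start=iv.start, end=iv.end, label=names[state],
            score=_mean(r.score[state] for r in run), color=colors[state],
            tooltip=f"{names[state]} {iv.start}–{iv.end}"))
    return AnnotationRow(label=label, annotations=tuple(anns))


def pc2_to_row(records: Sequence[ResidueStateRecord],
               p_threshold: float = DEFAULT_P_THRESHOLD,
               label: str = "coiled coil") -> AnnotationRow:
    """Maximal runs of residues with p-score <= threshold; a run is scored by
    its minimum p-score (the best evidence in the region)."""
    if p_threshold <= 0:
        raise ParameterError(f"p-score threshold must be > 0, got {p_threshold}")
    anns = []
    for iv, run in runs_of(records, lambda r: r.score <= p_threshold):
        anns.append(FeatureAnnotation(
            start=iv.start, end=iv.end, label="coiled coil",
            score=min(r.score for r in run), color=COILED_COIL_COLOR,
            tooltip=f"coiled coil {iv.start}–{iv.end}"))
    return AnnotationRow(label=label, annotations=tuple(anns))


def diso_to_row(records: Sequence[ResidueStateRecord],
                label: str = "disorder") -> AnnotationRow:
    """Maximal runs of residues marked disordered ('*'), scored by mean
    confidence."""
    anns = []
    for iv, run in runs_of(records, lambda r: r.state == "*"):
        anns.append(FeatureAnnotation(
            start=iv.start, end=iv.end, label="disordered",
            score=_mean(r.score for r in run), color=DISORDER_COLOR,
            tooltip=f"disordered {iv.start}–{iv.end}"))
    return AnnotationRow(label=label, annotations=tuple(anns))


FORMATS = ("ss2", "pc2", "diso")


def convert(text: str, format: str, *, p_threshold: float | None = None,
            label: str | None = None, title: str = "") -> ViewerSpec:
    """Parse ``text`` in the named dialect and wrap the converted row in a
    one-row :class:`ViewerSpec` whose length is the residue count."""
    if format != "pc2" and p_threshold is not None:
        raise ParameterError("--p-threshold applies to the pc2 format only")
    if format == "ss2":
        records = read_ss2(text)
        row = ss2_to_row(records, label=label or "secondary structure")
    elif format == "pc2":
        records = read_pc2(text)
        row = pc2_to_row(records,
                         p_threshold=DEFAULT_P_THRESHOLD if p_threshold is None
                         else p_threshold,
                         label=label or "coiled coil")
    elif format == "diso":
        records = read_diso(text)
        row = diso_to_row(records, label=label or "disorder")
    else:
        raise ParameterError(f"unknown format {format!r}; expected one of {FORMATS}")
    return ViewerSpec(sequence_length=len(records), rows=(row,), title=title)
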
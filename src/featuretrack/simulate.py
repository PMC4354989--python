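"""Deterministic generators of annotation sets and prediction files.

Everything here is a statistical fixture, not a biophysical simulation:
state runs and scores are drawn from simple seeded distributions so that
every other module can be exercised without downloads.  A fixed seed always
reproduces the same output, and each format generator returns both the text
it emitted and the ground-truth row a converter must recover from it — the
truth is bookkept from the generator's own run structure, never by calling
the converter.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .errors import ParameterError
from .layout import Interval, max_depth
from .model import (AnnotationRow, FeatureAnnotation, MarkerLine, SummaryValue,
                    ViewerSpec, normalize_row, normalize_viewer)
from .readers import (COILED_COIL_COLOR, DISORDER_COLOR, HELIX_COLOR,
                      STRAND_COLOR)

__all__ = ["GeneratorParams", "gen_viewer", "gen_format_file"]

_PALETTE = ("#d62728", "#9467bd", "#e6b000", "#2ca05a", "#00b5c8", "#000000")
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the deterministic generators.

    ``target_max_depth`` is the deepest overlap stack any row of a generated
    viewer attains (1 means all rows are overlap-free); run lengths for the
    per-residue format emitters are uniform on ``run_length_range``.
    """

    seed: int = 0
    sequence_length: int = 400
    n_rows: int = 4
    annotations_per_row: int = 6
    target_max_depth: int = 3
    score_range: tuple[float, float] = (0.0, 1.0)
    run_length_range: tuple[int, int] = (3, 12)

    def __post_init__(self):
        if self.sequence_length < 1 or self.n_rows < 1:
            raise ParameterError("sequence_length and n_rows must be >= 1")
        if not 1 <= self.target_max_depth <= self.annotations_per_row:
            raise ParameterError(
                "need 1 <= target_max_depth <= annotations_per_row")
        if self.run_length_range[0] < 1:
            raise ParameterError("run lengths must be >= 1")


def _lane_intervals(rng: random.Random, n: int, n_lanes: int,
                    length: int) -> list[Interval]:
    """Random intervals with overlap depth <= n_lanes, by per-lane cursors."""
    cursors = [1] * n_lanes
    out: list[Interval] = []
    for _ in range(n):
        open_lanes = [l for l in range(n_lanes) if cursors[l] <= length]
        if not open_lanes:
            raise ParameterError(
                f"sequence_length {length} too short for {n} annotations "
                f"over {n_lanes} lanes")
        lane = rng.choice(open_lanes)
        start = min(cursors[lane] + rng.randint(0, 6), length)
        end = min(start + rng.randint(0, max(2, length // (2 * n)) - 1), length)
        cursors[lane] = end + 2  # +2: same-lane neighbours never touch
        out.append(Interval(start, end))
    return out


def _stacked_intervals(rng: random.Random, n: int, depth: int,
                       length: int) -> list[Interval]:
    """Exactly ``depth`` intervals sharing one anchor position, remaining
    intervals pairwise disjoint and clear of the stack."""
    if length < 3 * depth + 3 * (n - depth) + 2:
        raise ParameterError(
            f"sequence_length {length} too short for {n} annotations "
            f"at depth {depth}")
    anchor = rng.randint(length // 3, 2 * length // 3)
    stack = []
    for _ in range(depth):
        s = rng.randint(max(1, anchor - length // 8), anchor)
        e = rng.randint(anchor, min(length, anchor + length // 8))
        stack.append(Interval(s, e))
    lo = min(iv.start for iv in stack)
    hi = max(iv.end for iv in stack)
    # disjoint filler intervals left and right of the stack
    filler: list[Interval] = []
    cursor = 1
    for _ in range(n - depth):
        if cursor + 1 < lo - 1:
            end = min(cursor + rng.randint(0, 4), lo - 2)
            filler.append(Interval(cursor, end))
            cursor = end + 2
        elif hi + 2 <= length:
            start = hi + 2 if not filler or filler[-1].end < hi else filler[-1].end + 2
            start = max(start, hi + 2)
            if start > length:
                break
            end = min(start + rng.randint(0, 4), length)
            filler.append(Interval(start, end))
            hi = end
    return stack + filler


def gen_viewer(params: GeneratorParams = GeneratorParams()) -> ViewerSpec:
    """A valid random viewer whose deepest row attains exactly
    ``target_max_depth``; deterministic in the seed."""
    rng = random.Random(params.seed)
    L = params.sequence_length
    rows = []
    for i in range(params.n_rows):
        if i == 0:
            ivs = _stacked_intervals(rng, params.annotations_per_row,
                                     params.target_max_depth, L)
        else:
            ivs = _lane_intervals(rng, params.annotations_per_row,
                                  params.target_max_depth, L)
        rng.shuffle(ivs)
        lo, hi = params.score_range
        anns = tuple(
            FeatureAnnotation(
                start=iv.start, end=iv.end, label=f"feature {j + 1}",
                score=round(rng.uniform(lo, hi), 4),
                tooltip=f"feature {j + 1}: {iv.start}-{iv.end}" if rng.random() < 0.5 else None,
                url=f"https://example.org/f/{i}/{j}" if rng.random() < 0.3 else None)
            for j, iv in enumerate(ivs))
        summary = (SummaryValue(value=round(rng.random(), 4),
                                label=f"coverage {i + 1}")
                   if rng.random() < 0.7 else None)
        rows.append(AnnotationRow(
            label=f"run {i + 1}", annotations=anns, summary=summary,
            default_color=rng.choice(_PALETTE)))
    markers = tuple(MarkerLine(position=rng.randint(1, L))
                    for _ in range(rng.randint(0, 3)))
    spec = ViewerSpec(sequence_length=L, rows=tuple(rows),
                      title=f"synthetic viewer (seed {params.seed})",
                      markers=markers)
    spec = normalize_viewer(spec)
    depths = [max_depth(r.annotations) for r in spec.rows]
    assert max(depths) == params.target_max_depth, depths
    return spec


def _run_states(rng: random.Random, params: GeneratorParams,
                alphabet: str, background: str) -> list[str]:
    """Per-residue states of length ~sequence_length built from random runs."""
    states: list[str] = []
    while len(states) < params.sequence_length:
        state = rng.choice(alphabet) if rng.random() < 0.5 else background
        run = rng.randint(*params.run_length_range)
        states.extend([state] * run)
    return states[: params.sequence_length]


def gen_format_file(params: GeneratorParams, format: str,
                    p_threshold: float = 0.025
                    ) -> tuple[str, AnnotationRow]:
    """Emit one dialect-conformant prediction file plus its ground truth.

    The returned row is what the matching converter must recover from the
    text (for pc2, at the given ``p_threshold``); it is computed from the
    generator's own bookkeeping of states and scores.
    """
    fmt_salt = {"ss2": 1, "pc2": 2, "diso": 3}.get(format)
    if fmt_salt is None:
        raise ParameterError(f"unknown format {format!r}")
    rng = random.Random(params.seed * 8 + fmt_salt)
    n = params.sequence_length
    residues = [rng.choice(_AA) for _ in range(n)]

    if format == "ss2":
        states = _run_states(rng, params, "HE", "C")
        lines = ["# PSIPRED VFORMAT (synthetic fixture)", ""]
        scores = []
        for i in range(n):
            triple = {"C": 0.1, "H": 0.1, "E": 0.1}
            triple[states[i]] = round(rng.uniform(0.5, 1.0), 3)
            scores.append(triple)
            lines.append(f"{i + 1:4d} {residues[i]} {states[i]}  "
                         f"{triple['C']:6.3f} {triple['H']:6.3f} {triple['E']:6.3f}")
        truth = _truth_runs(states, lambda s: s in "HE", group=True,
                            score_of=lambda i, s: scores[i][s],
                            names={"H": "helix", "E": "strand"},
                            colors={"H": HELIX_COLOR, "E": STRAND_COLOR},
                            agg="mean")
        return "\n".join(lines) + "\n", AnnotationRow("secondary structure", truth)

    if format == "pc2":
        lines = ["# Paircoil2 output (synthetic fixture)"]
        pscores = []
        for i in range(n):
            # mixture: confident coiled-coil stretches get tiny p-scores
            p = round(rng.uniform(1e-4, p_threshold), 5) if rng.random() < 0.3 \
                else round(rng.uniform(p_threshold * 2, 1.0), 5)
            pscores.append(p)
            lines.append(f"{i + 1:4d} {residues[i]} {'abcdefg'[i % 7]} {p:.5f}")
        states = ["*" if p <= p_threshold else "." for p in pscores]
        truth = _truth_runs(states, lambda s: s == "*", group=False,
                            score_of=lambda i, s: pscores[i],
                            names={"*": "coiled coil"},
                            colors={"*": COILED_COIL_COLOR}, agg="min")
        return "\n".join(lines) + "\n", AnnotationRow("coiled coil", truth)

    if format == "diso":
        states = _run_states(rng, params, "*", ".")
        lines = ["# DISOPRED (synthetic fixture)"]
        confs = []
        for i in range(n):
            c = round(rng.uniform(0.5, 1.0) if states[i] == "*"
                      else rng.uniform(0.0, 0.5), 3)
            confs.append(c)
            lines.append(f"{i + 1:4d} {residues[i]} {states[i]} {c:.3f}")
        truth = _truth_runs(states, lambda s: s == "*", group=False,
                            score_of=lambda i, s: confs[i],
                            names={"*": "disordered"},
                            colors={"*": DISORDER_COLOR}, agg="mean")
        return "\n".join(lines) + "\n", AnnotationRow("disorder", truth)

    raise ParameterError(f"unknown format {format!r}")


def _truth_runs(states, keep, group, score_of, names, colors, agg):
    """Ground-truth annotations from a state list, by direct run scanning."""
    anns = []
    i, n = 0, len(states)
    while i < n:
        if not keep(states[i]):
            i += 1
            continue
        j = i
        while (j + 1 < n and keep(states[j + 1])
               and (not group or states[j + 1] == states[i])):
            j += 1
        run_scores = [score_of(k, states[i]) for k in range(i, j + 1)]
        score = min(run_scores) if agg == "min" else sum(run_scores) / len(run_scores)
        name = names[states[i]]
        anns.append(FeatureAnnotation(
            start=i + 1, end=j + 1, label=name, score=score,
            color=colors[states[i]], tooltip=f"{name} {i + 1}–{j + 1}"))
        i = j + 1
    return tuple(anns)
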
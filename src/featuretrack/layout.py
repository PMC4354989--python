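"""Interval algorithms behind collapsed and expanded annotation rows.

All coordinates are 1-based and inclusive, so two intervals *overlap* iff
they share at least one sequence position: ``(1,5)`` and ``(6,9)`` abut
visually but do not overlap, and trigger no expand indicator.

The collapsed view of a row shows :func:`merge_blocks` — the minimal set of
disjoint blocks covering the same positions as the input (e.g. annotations
2-10 and 8-19 appear as the single block 2-19).  The expanded view shows one
lane ("sub-track") per :func:`assign_tracks` index; greedy first-fit on
intervals sorted by (start, end, input order) is optimal for interval graphs,
so the number of sub-tracks always equals :func:`max_depth`, the largest
number of annotations stacked over any single position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

__all__ = [
    "Interval",
    "MergedBlock",
    "TrackAssignment",
    "overlaps",
    "overlap_region",
    "merge_blocks",
    "has_overlaps",
    "assign_tracks",
    "max_depth",
]


class Interval(NamedTuple):
    start: int
    end: int


@dataclass(frozen=True)
class MergedBlock:
    """A maximal run of mutually connected intervals; ``members`` holds the
    input indices of the annotations it covers."""

    start: int
    end: int
    members: tuple[int, ...]


@dataclass(frozen=True)
class TrackAssignment:
    """``track_index[i]`` is the 0-based sub-track of input interval ``i``;
    indices are dense, so ``n_tracks == 1 + max(track_index)``."""

    track_index: tuple[int, ...]
    n_tracks: int


def _as_intervals(items: Iterable) -> list[Interval]:
    out = []
    for it in items:
        iv = Interval(it.start, it.end) if not isinstance(it, Interval) else it
        if iv.start > iv.end:
            raise ValueError(f"invalid interval {iv}: start > end")
        out.append(iv)
    return out


def overlaps(a: Interval, b: Interval) -> bool:
    """True iff the two inclusive intervals share at least one position."""
    return a.start <= b.end and b.start <= a.end


def overlap_region(a: Interval, b: Interval) -> Interval | None:
    """The shared region ``(max starts, min ends)``, or None when disjoint."""
    if not overlaps(a, b):
        return None
    return Interval(max(a.start, b.start), min(a.end, b.end))


def merge_blocks(intervals: Sequence) -> list[MergedBlock]:
    """Merge overlapping intervals into disjoint blocks, keeping strictly
    adjacent intervals separate; each block records its member input indices.
    """
    ivs = _as_intervals(intervals)
    order = sorted(range(len(ivs)), key=lambda i: (ivs[i].start, ivs[i].end, i))
    blocks: list[MergedBlock] = []
    cur_start = cur_end = 0
    cur_members: list[int] = []
    for i in order:
        iv = ivs[i]
        if cur_members and iv.start <= cur_end:
            cur_end = max(cur_end, iv.end)
            cur_members.append(i)
        else:
            if cur_members:
                blocks.append(MergedBlock(cur_start, cur_end, tuple(cur_members)))
            cur_start, cur_end, cur_members = iv.start, iv.end, [i]
    if cur_members:
        blocks.append(MergedBlock(cur_start, cur_end, tuple(cur_members)))
    return blocks


def has_overlaps(intervals: Sequence) -> bool:
    """True iff any pair of intervals overlaps (drives the expand indicator)."""
    ivs = sorted(_as_intervals(intervals))
    return any(b.start <= a.end for a, b in zip(ivs, ivs[1:]))


def assign_tracks(intervals: Sequence) -> TrackAssignment:
    """Pack intervals onto sub-tracks by greedy first-fit.

    Intervals are visited in (start, end, input index) order and each takes
    the lowest-numbered track whose previously placed intervals it does not
    overlap.  On intervals this greedy sweep uses exactly ``max_depth``
    tracks, the minimum possible.  The result is indexed by original input
    order.
    """
    ivs = _as_intervals(intervals)
    order = sorted(range(len(ivs)), key=lambda i: (ivs[i].start, ivs[i].end, i))
    track_of = [0] * len(ivs)
    last_end: list[int] = []  # rightmost occupied position per track
    for i in order:
        iv = ivs[i]
        for t, end in enumerate(last_end):
            if iv.start > end:
                track_of[i] = t
                last_end[t] = iv.end
                break
        else:
            track_of[i] = len(last_end)
            last_end.append(iv.end)
    return TrackAssignment(tuple(track_of), len(last_end))


def max_depth(intervals: Sequence) -> int:
    """Maximum number of intervals covering any one position (0 if empty)."""
    ivs = _as_intervals(intervals)
    if not ivs:
        return 0
    events = sorted([(iv.start, 1) for iv in ivs] + [(iv.end + 1, -1) for iv in ivs])
    depth = best = 0
    for _, delta in events:
        depth += delta
        best = max(best, depth)
    return best
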
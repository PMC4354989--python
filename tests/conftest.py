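import random

import pytest
from hypothesis import HealthCheck, settings, strategies as st

from featuretrack.layout import Interval
from featuretrack.model import (AnnotationRow, FeatureAnnotation, MarkerLine,
                                SummaryValue, ViewerSpec)

settings.register_profile(
    "default", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")

# optional text fields: the JSON dialect treats "" as absent, so generated
# optional strings are either None or non-empty
_text = st.text(st.characters(codec="ascii", min_codepoint=32, max_codepoint=126),
                min_size=1, max_size=12)
_opt_text = st.none() | _text
_score = st.none() | st.floats(allow_nan=False, allow_infinity=False,
                               min_value=-1e6, max_value=1e6)


@st.composite
def intervals(draw, max_length: int = 200):
    start = draw(st.integers(1, max_length))
    end = draw(st.integers(start, max_length))
    return Interval(start, end)


@st.composite
def interval_lists(draw, max_n: int = 12, max_length: int = 200):
    return draw(st.lists(intervals(max_length), max_size=max_n))


@st.composite
def annotations(draw, length: int):
    start = draw(st.integers(1, length))
    end = draw(st.integers(start, length))
    return FeatureAnnotation(
        start=start, end=end, label=draw(_text | st.just("")),
        score=draw(_score), color=draw(_opt_text), tooltip=draw(_opt_text),
        url=draw(_opt_text))


@st.composite
def viewer_specs(draw, max_length: int = 150, max_rows: int = 4):
    length = draw(st.integers(1, max_length))
    rows = []
    for i in range(draw(st.integers(0, max_rows))):
        anns = draw(st.lists(annotations(length), max_size=6))
        summary = draw(st.none() | st.builds(
            SummaryValue, value=st.floats(0, 1, allow_nan=False),
            label=_text | st.just(""), color=_opt_text,
            tooltip=_opt_text, url=_opt_text))
        rows.append(AnnotationRow(label=draw(_text), annotations=tuple(anns),
                                  summary=summary, default_color=draw(_opt_text)))
    markers = draw(st.lists(st.builds(
        MarkerLine, position=st.integers(1, length), color=_opt_text,
        label=_opt_text), max_size=3))
    return ViewerSpec(sequence_length=length, rows=tuple(rows),
                      title=draw(_text | st.just("")), markers=tuple(markers))


@pytest.fixture
def rng():
    return random.Random(20150307)


def random_interval_set(rng: random.Random, n: int, length: int = 60):
    out = []
    for _ in range(n):
        s = rng.randint(1, length)
        out.append(Interval(s, rng.randint(s, min(length, s + rng.randint(0, 20)))))
    return out


# --- independent oracles used by layout and acceptance tests --------------

def covered_positions(ivs):
    """Brute-force union of inclusive position sets."""
    out = set()
    for iv in ivs:
        out.update(range(iv.start, iv.end + 1))
    return out


def depth_by_counting(ivs):
    """Per-position counting oracle for maximum overlap depth."""
    if not ivs:
        return 0
    counts = {}
    for iv in ivs:
        for p in range(iv.start, iv.end + 1):
            counts[p] = counts.get(p, 0) + 1
    return max(counts.values())


def exact_min_tracks(ivs):
    """Exhaustive-search minimum number of conflict-free tracks (n <= ~8).

    Backtracking coloring of the interval-overlap graph; independent of the
    greedy sweep it cross-checks.
    """
    n = len(ivs)
    if n == 0:
        return 0
    conflict = [[a.start <= b.end and b.start <= a.end for b in ivs] for a in ivs]
    for k in range(1, n + 1):
        colors = [-1] * n

        def feasible(i):
            if i == n:
                return True
            used = {colors[j] for j in range(i) if conflict[i][j]}
            for c in range(k):
                if c not in used:
                    colors[i] = c
                    if feasible(i + 1):
                        return True
            colors[i] = -1
            return False

        if feasible(0):
            return k
    return n
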
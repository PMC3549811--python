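"""Half-open interval algebra on the normalized genome [0, 1].

Every sequence coordinate in this package lives on the unit interval: a
simulated chromosome of ``sequence_length_bp`` base pairs is rescaled so that
position 0 is the left end and 1.0 the right end.  Ancestral material carried
by an ARG edge is a sorted, disjoint list of half-open intervals ``[a, b)``.

Intervals are plain ``(start, end)`` float tuples; interval *lists* are
tuples of such pairs.  All functions preserve the canonical form: sorted by
start, pairwise disjoint, with abutting intervals coalesced.
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Iterable, Sequence

Interval = tuple[float, float]
IntervalList = tuple[Interval, ...]


def canonical(intervals: Iterable[Sequence[float]]) -> IntervalList:
    """Sort, drop empty, and coalesce overlapping/abutting intervals."""
    ivs = sorted((float(a), float(b)) for a, b in intervals if a < b)
    out: list[Interval] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            if b > out[-1][1]:
                out[-1] = (out[-1][0], b)
        else:
            out.append((a, b))
    return tuple(out)


def is_canonical(intervals: Sequence[Sequence[float]]) -> bool:
    """True if sorted, disjoint and non-empty; abutting intervals allowed."""
    prev_end = None
    for a, b in intervals:
        if not (a < b):
            return False
        if prev_end is not None and a < prev_end:
            return False
        prev_end = b
    return True


def total_width(intervals: Sequence[Interval]) -> float:
    return sum(b - a for a, b in intervals)


def hull(intervals: Sequence[Interval]) -> Interval:
    """Smallest single interval containing all material (assumes canonical)."""
    if not intervals:
        raise ValueError("hull of empty material is undefined")
    return (intervals[0][0], intervals[-1][1])


def contains(intervals: Sequence[Interval], x: float) -> bool:
    """Membership of position ``x`` under half-open semantics."""
    for a, b in intervals:
        if a <= x < b:
            return True
        if a > x:
            return False
    return False


def strictly_inside(intervals: Sequence[Interval], x: float) -> bool:
    """True if ``x`` is interior to some interval (not on a boundary)."""
    return any(a < x < b for a, b in intervals)


def intersect(intervals: Sequence[Interval], lo: float, hi: float) -> IntervalList:
    """Restrict material to the window ``[lo, hi)``."""
    out = []
    for a, b in intervals:
        s, e = max(a, lo), min(b, hi)
        if s < e:
            out.append((s, e))
    return tuple(out)


def overlaps(intervals: Sequence[Interval], lo: float, hi: float) -> bool:
    """True if any material falls inside the window ``[lo, hi)``."""
    return any(max(a, lo) < min(b, hi) for a, b in intervals)


def union(*interval_lists: Sequence[Interval]) -> IntervalList:
    merged: list[Interval] = []
    for ivs in interval_lists:
        merged.extend(ivs)
    return canonical(merged)


def max_coverage_at_least(interval_lists: Sequence[Sequence[Interval]], k: int) -> bool:
    """True if some point of [0,1) is covered by >= ``k`` of the lists.

    Each list contributes coverage 1 on its own material (lists are assumed
    internally disjoint).  Used for the t-coalescent test: a node branches in
    some marginal tree iff two of its child edges overlap anywhere.
    """
    events: list[tuple[float, int]] = []
    for ivs in interval_lists:
        for a, b in ivs:
            events.append((a, 1))
            events.append((b, -1))
    events.sort()
    depth = 0
    for _, d in events:
        depth += d
        if depth >= k:
            return True
    return False


def boundaries(interval_lists: Iterable[Sequence[Interval]]) -> list[float]:
    """Distinct internal endpoints (excluding 0 and 1) across many lists."""
    pts = set()
    for ivs in interval_lists:
        for a, b in ivs:
            pts.add(a)
            pts.add(b)
    pts.discard(0.0)
    pts.discard(1.0)
    return sorted(pts)


def segment_index(breakpoints: Sequence[float], x: float) -> int:
    """Index of the nonmixing segment containing ``x``.

    ``breakpoints`` is the sorted list ``l_1 < ... < l_M = 1.0``; segment i is
    ``[l_{i-1}, l_i)`` with ``l_0 = 0``.
    """
    return bisect_right(breakpoints, x)
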
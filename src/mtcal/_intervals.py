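"""Half-open interval arithmetic on (start, end) tuples.

All functions operate on iterables of ``(start, end)`` pairs on a single
chromosome, 0-based half-open. They are deliberately simple sweep-line
implementations so their behaviour is easy to verify against brute force.
"""

from __future__ import annotations

from typing import Iterable, List, Tuple

Interval = Tuple[int, int]


def merge(intervals: Iterable[Interval]) -> List[Interval]:
    """Merge overlapping or touching intervals into a sorted disjoint list."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: List[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def subtract(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Return the footprint of ``a`` not covered by ``b`` (both merged first)."""
    a = merge(a)
    b = merge(b)
    out: List[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Intersection of two interval sets (merged, sorted)."""
    a = merge(a)
    b = merge(b)
    out: List[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge(intervals))


def clip(start: int, end: int, lo: int, hi: int) -> Interval | None:
    """Clip [start, end) to [lo, hi); None when empty."""
    s, e = max(start, lo), min(end, hi)
    return (s, e) if s < e else None
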
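"""Half-open interval arithmetic on (start, end) tuples.

All coordinates in this package are 0-based half-open. These helpers are the
single place merging/subtraction/complement logic lives; every module that
annotates features against the genome goes through them.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping

from intervaltree import IntervalTree

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or book-ended intervals into a sorted disjoint list."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    if not ivs:
        return []
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def subtract_intervals(base: Iterable[Interval], holes: Iterable[Interval]) -> list[Interval]:
    """base minus holes; both may be unsorted/overlapping."""
    base_m = merge_intervals(base)
    holes_m = merge_intervals(holes)
    out: list[Interval] = []
    hi = 0
    for s, e in base_m:
        cur = s
        while hi < len(holes_m) and holes_m[hi][1] <= cur:
            hi += 1
        j = hi
        while j < len(holes_m) and holes_m[j][0] < e:
            hs, he = holes_m[j]
            if hs > cur:
                out.append((cur, hs))
            cur = max(cur, he)
            if cur >= e:
                break
            j += 1
        if cur < e:
            out.append((cur, e))
    return out


def complement_intervals(intervals: Iterable[Interval], length: int) -> list[Interval]:
    return subtract_intervals([(0, length)], intervals)


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def clip(start: int, end: int, length: int) -> Interval | None:
    s, e = max(0, start), min(length, end)
    return (s, e) if s < e else None


def overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


class GenomeIntervals:
    """Per-chromosome interval trees over labelled intervals.

    ``data`` values may be anything hashable (a label, an index).
    """

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)

    @classmethod
    def from_mapping(cls, per_chrom: Mapping[str, Iterable[Interval]], data=None) -> "GenomeIntervals":
        gi = cls()
        for chrom, ivs in per_chrom.items():
            for s, e in ivs:
                gi.add(chrom, s, e, data)
        return gi

    def add(self, chrom: str, start: int, end: int, data=None) -> None:
        if end > start:
            self._trees[chrom].addi(start, end, data)

    def query(self, chrom: str, start: int, end: int) -> list:
        """Return data payloads of intervals overlapping [start, end) by >= 1 bp."""
        if chrom not in self._trees:
            return []
        return [iv.data for iv in self._trees[chrom].overlap(start, end)]

    def any_overlap(self, chrom: str, start: int, end: int) -> bool:
        return chrom in self._trees and bool(self._trees[chrom].overlap(start, end))
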
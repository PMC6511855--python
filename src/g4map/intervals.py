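"""Small interval helpers shared by feature derivation and enrichment.

All coordinates are 0-based half-open.  Merging is per-chromosome; overlap
queries run on the merged, sorted representation via binary search.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np

__all__ = ["merge_intervals", "union_length", "MergedIntervals"]


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or bookended intervals into a sorted disjoint list."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


class MergedIntervals:
    """Per-chromosome merged intervals supporting O(log n) overlap queries."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for chrom, s, e in intervals:
            by_chrom[chrom].append((s, e))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self.total_length = 0
        for chrom, ivs in by_chrom.items():
            merged = merge_intervals(ivs)
            self._starts[chrom] = np.array([s for s, _ in merged], dtype=np.int64)
            self._ends[chrom] = np.array([e for _, e in merged], dtype=np.int64)
            self.total_length += sum(e - s for s, e in merged)

    def chroms(self) -> Sequence[str]:
        return list(self._starts)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) overlaps any merged interval by >= 1 bp."""
        if chrom not in self._starts:
            return False
        starts, ends = self._starts[chrom], self._ends[chrom]
        # first interval whose end is > start
        i = int(np.searchsorted(ends, start, side="right"))
        return i < len(starts) and starts[i] < end
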
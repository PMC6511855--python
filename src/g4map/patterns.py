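"""Consensus-pattern matching and G-run censuses.

The classical quadruplex consensus ("Quadparser-style") asks for four runs
of at least three guanines separated by loops of one to seven nucleotides.
Here a candidate G-tract is a MAXIMAL run of guanines: a single uninterrupted
run can never supply two tracts, because tracts must be separated by a loop
of at least ``loop_min`` bases.  Loops may themselves contain guanines
(including whole shorter runs) — the consensus constrains tract length and
loop length, not loop composition.

Matching chains maximal runs with a forward scan over run indices, which is
equivalent to exhaustively enumerating run subsets (runs are totally ordered
by position, so any valid chain is found).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .regions import G4Region
from .scoring import _validate, reverse_complement

__all__ = [
    "QuadparserPattern",
    "quadparser_match",
    "g_run_census",
    "multi_g4run_regions",
]

_G_RUN_RE = re.compile(r"G+")


@dataclass(frozen=True)
class QuadparserPattern:
    """Consensus parameters: n_runs runs of >= min_run G, loops loop_min..loop_max."""

    min_run: int = 3
    loop_min: int = 1
    loop_max: int = 7
    n_runs: int = 4

    def __post_init__(self) -> None:
        if self.min_run < 2:
            raise ValueError("min_run must be >= 2")
        if not (0 < self.loop_min <= self.loop_max):
            raise ValueError("need 0 < loop_min <= loop_max")
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")


def _maximal_g_runs(seq: str, min_len: int) -> list[tuple[int, int]]:
    return [
        (m.start(), m.end())
        for m in _G_RUN_RE.finditer(seq)
        if m.end() - m.start() >= min_len
    ]


def _chain_spans(
    runs: Sequence[tuple[int, int]], pattern: QuadparserPattern
) -> list[tuple[int, int]]:
    """All (start, end) spans of valid chains of exactly n_runs tracts.

    Chains are built left to right; consecutive chosen tracts must be
    separated by loop_min..loop_max bases (intervening shorter runs fall
    inside the loop).  Returns the minimal span per distinct chain start.
    """
    spans: list[tuple[int, int]] = []
    n = len(runs)

    def extend(idx: int, depth: int, chain_start: int) -> int | None:
        """Earliest end coordinate of a chain of remaining depth from runs[idx]."""
        if depth == 1:
            return runs[idx][1]
        for j in range(idx + 1, n):
            gap = runs[j][0] - runs[idx][1]
            if gap > pattern.loop_max:
                break
            if gap >= pattern.loop_min:
                end = extend(j, depth - 1, chain_start)
                if end is not None:
                    return end
        return None

    for i in range(n):
        end = extend(i, pattern.n_runs, runs[i][0])
        if end is not None:
            spans.append((runs[i][0], end))
    return spans


def quadparser_match(
    sequence: str,
    pattern: QuadparserPattern = QuadparserPattern(),
    include_c_strand: bool = False,
) -> tuple[bool, list[tuple[int, int]]]:
    """Test a sequence against the consensus; returns (matched, spans).

    U is mapped to T before matching.  With *include_c_strand* the reverse
    complement is also tested and its matches are reported in forward
    coordinates.
    """
    seq = _validate(sequence).replace("U", "T")
    runs = _maximal_g_runs(seq, pattern.min_run)
    spans = _chain_spans(runs, pattern)
    if include_c_strand:
        rc = reverse_complement(seq)
        rc_runs = _maximal_g_runs(rc, pattern.min_run)
        L = len(seq)
        spans += [(L - e, L - s) for s, e in _chain_spans(rc_runs, pattern)]
        spans.sort()
    return bool(spans), spans


def g_run_census(sequence: str, min_len: int = 4) -> list[tuple[int, int]]:
    """Maximal G runs of length >= min_len as (start, length), in order."""
    seq = _validate(sequence).replace("U", "T")
    return [(s, e - s) for s, e in _maximal_g_runs(seq, min_len)]


def multi_g4run_regions(
    items: Sequence[str] | Sequence[tuple[G4Region, str]],
    min_len: int = 4,
    min_runs: int = 2,
    check_reverse: bool = False,
) -> list:
    """Keep items whose sequence carries >= min_runs maximal G runs >= min_len.

    Items are plain sequences or (region, sequence) pairs; with
    *check_reverse* the reverse complement is also censused, so C-run-rich
    items (quadruplex on the other strand) qualify too.
    """
    kept = []
    for item in items:
        seq = item[1] if isinstance(item, tuple) else item
        if not seq:
            continue
        n = len(g_run_census(seq, min_len))
        if check_reverse:
            n = max(n, len(g_run_census(reverse_complement(seq), min_len)))
        if n >= min_runs:
            kept.append(item)
    return kept
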
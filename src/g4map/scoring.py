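"""G4Hunter per-base scoring and sliding-window means.

The G4Hunter score of a nucleic-acid sequence measures both G-richness and
GC skewness: every base inside a maximal run of *n* consecutive guanines
scores ``min(n, 4)``, every base inside a maximal run of *n* cytosines scores
``-min(n, 4)``, and all other bases (A, T, U, N and IUPAC ambiguity codes)
score 0.  The score of a sequence is the arithmetic mean of its per-base
scores; a positive score marks a G-rich (quadruplex-prone) sequence on the
given strand, a negative score marks the complementary-strand mirror.

Genome scans average the per-base track over a sliding window (default
25 nt).  Base scores are computed once from maximal runs in the *full*
sequence; windows average that global track, so a G-run is never truncated
at a window edge (``truncate_runs=True`` opts into per-window truncation).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BaseScoreTrack",
    "ScanParams",
    "base_scores",
    "sequence_score",
    "window_scores",
    "format_score",
    "reverse_complement",
]

# Accepted alphabet: canonical bases, U, and IUPAC ambiguity codes.
_ALPHABET = set("ACGTUNRYSWKMBDHV")

_RUN_RE = re.compile(r"G+|C+")

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)


def _validate(sequence: str) -> str:
    """Uppercase the sequence and reject characters outside the alphabet."""
    if not sequence:
        raise ValueError("empty input")
    seq = sequence.upper()
    for pos, ch in enumerate(seq):
        if ch not in _ALPHABET:
            raise ValueError(
                f"invalid character {ch!r} at position {pos} "
                "(expected A/C/G/T/U/N or IUPAC ambiguity code)"
            )
    return seq


@dataclass
class BaseScoreTrack:
    """Per-base integer G4Hunter scores for one sequence.

    Scores are in [-4, 4]; every non-G/C base scores 0 and every base of a
    maximal G (C) run of length n scores +min(n,4) (-min(n,4)).
    """

    sequence_id: str
    scores: np.ndarray  # int8, one entry per base

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int8)

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def mean(self) -> float:
        return float(self.scores.sum(dtype=np.int64)) / len(self.scores)


@dataclass(frozen=True)
class ScanParams:
    """Parameters of a genome G4 scan.

    window_length
        Sliding-window size in bases (default 25 nt).
    thresholds
        Absolute window-mean cutoffs used to call hits; scans are run
        independently per threshold.
    min_gap_to_merge
        Qualifying windows closer than this (in bases) are merged into one
        region; 0 merges only overlapping/bookended windows.
    truncate_runs
        If True, recompute runs within each window instead of slicing the
        global track (marginally changes genome-wide counts).
    """

    window_length: int = 25
    thresholds: tuple[float, ...] = (1.2, 1.5, 1.75, 2.0)
    min_gap_to_merge: int = 0
    truncate_runs: bool = False

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        if any(t <= 0 for t in self.thresholds):
            raise ValueError("thresholds must be positive")


def base_scores(sequence: str, sequence_id: str = "") -> BaseScoreTrack:
    """Score every base of *sequence* by the G4Hunter run rule.

    U is treated as T (scores 0); input is case-insensitive.  Raises
    ``ValueError`` on an empty sequence or a character outside the accepted
    alphabet (naming the character and its position).
    """
    seq = _validate(sequence)
    scores = np.zeros(len(seq), dtype=np.int8)
    for m in _RUN_RE.finditer(seq):
        run_len = m.end() - m.start()
        value = min(run_len, 4)
        if m.group()[0] == "C":
            value = -value
        scores[m.start() : m.end()] = value
    return BaseScoreTrack(sequence_id=sequence_id, scores=scores)


def sequence_score(sequence: str) -> float:
    """Full-sequence G4Hunter score: the mean of the per-base scores."""
    return base_scores(sequence).mean


def format_score(score: float) -> str:
    """Render a score at 2 decimals (round-half-to-even) for reports."""
    return f"{round(score, 2):.2f}"


def reverse_complement(sequence: str) -> str:
    """Reverse complement, preserving case and IUPAC ambiguity codes."""
    return sequence.translate(_COMPLEMENT)[::-1]


def window_scores(track: BaseScoreTrack, params: ScanParams) -> np.ndarray:
    """Sliding-window means of a per-base score track.

    For a track of length L >= W returns L-W+1 values where value *i* is the
    mean of ``scores[i:i+W]``; for L < W returns the single full-track mean.
    Window sums are exact integer prefix-sum differences, so the result is
    bit-identical to a naive per-window recomputation.
    """
    w = params.window_length
    s = track.scores.astype(np.int64)
    if len(s) < w:
        return np.array([track.mean])
    prefix = np.concatenate(([0], np.cumsum(s)))
    return (prefix[w:] - prefix[:-w]) / float(w)
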
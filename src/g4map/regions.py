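"""Calling discrete G4-prone regions (G4FS) from window scores.

A scan slides a window over the per-base score track; every window whose
mean score reaches the threshold in absolute value qualifies.  Overlapping
or bookended qualifying windows of the same sign are merged into one maximal
region — the unit of counting is the merged motif, not the window.  Opposite-sign windows are never merged: a +1 region is G-rich on
the reference strand, a -1 region is C-rich there (a quadruplex on the
reverse strand).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .scoring import ScanParams, base_scores, sequence_score, window_scores

__all__ = ["G4Region", "find_hits", "hits_by_threshold", "write_regions", "read_regions"]

_TSV_FIELDS = (
    "chrom",
    "start",
    "end",
    "sign",
    "region_score",
    "max_window_score",
    "threshold",
)


@dataclass(frozen=True)
class G4Region:
    """One called G4-prone motif in 0-based half-open coordinates.

    ``sign`` is +1 when the reference forward strand is G-rich and -1 when it
    is C-rich (the quadruplex then lies on the reverse strand).
    ``region_score`` is the full-sequence G4Hunter score of the merged span;
    merging can pull it below the calling threshold, but
    ``abs(max_window_score)`` always reaches the threshold.
    """

    chrom: str
    start: int
    end: int
    sign: int
    region_score: float
    max_window_score: float
    threshold: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")


def _windows_naive(seq: str, w: int) -> np.ndarray:
    """Window means with runs truncated at window edges (option path)."""
    if len(seq) < w:
        return np.array([sequence_score(seq)])
    return np.array([sequence_score(seq[i : i + w]) for i in range(len(seq) - w + 1)])


def find_hits(
    chrom_sequence: str,
    chrom_name: str,
    params: ScanParams,
    threshold: float,
) -> list[G4Region]:
    """Scan one chromosome at one threshold and return merged hit regions.

    A chromosome shorter than the window is scanned as a single window.
    Raises ``ValueError`` on an empty sequence or non-positive threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    track = base_scores(chrom_sequence, sequence_id=chrom_name)
    if params.truncate_runs:
        wmeans = _windows_naive(chrom_sequence.upper().replace("U", "T"), params.window_length)
    else:
        wmeans = window_scores(track, params)
    w = min(params.window_length, len(track))
    qualifying = np.flatnonzero(np.abs(wmeans) >= threshold)
    if qualifying.size == 0:
        return []
    signs = np.sign(wmeans[qualifying]).astype(int)

    regions: list[G4Region] = []
    seq = chrom_sequence.upper()
    # merge same-sign windows that overlap, are bookended, or sit within
    # min_gap_to_merge bases of the previous window's end
    run_start = int(qualifying[0])
    run_end = run_start + w
    run_sign = int(signs[0])
    best = float(wmeans[qualifying[0]])

    def _flush() -> None:
        sub = seq[run_start:run_end]
        regions.append(
            G4Region(
                chrom=chrom_name,
                start=run_start,
                end=run_end,
                sign=run_sign,
                region_score=sequence_score(sub),
                max_window_score=best,
                threshold=threshold,
            )
        )

    for idx, sgn in zip(qualifying[1:], signs[1:]):
        idx = int(idx)
        if sgn == run_sign and idx - run_end <= params.min_gap_to_merge:
            run_end = idx + w
            if abs(wmeans[idx]) > abs(best):
                best = float(wmeans[idx])
        else:
            _flush()
            run_start, run_end, run_sign = idx, idx + w, int(sgn)
            best = float(wmeans[idx])
    _flush()
    regions.sort(key=lambda r: r.start)
    return regions


def hits_by_threshold(
    genome: Mapping[str, str],
    params: ScanParams,
    thresholds: Iterable[float] | None = None,
) -> dict[float, list[G4Region]]:
    """Scan every chromosome independently at every threshold.

    Each threshold is a full scan, not a filtering of a lower threshold's
    regions, because merging differs between thresholds.
    """
    ts = sorted(thresholds if thresholds is not None else params.thresholds)
    out: dict[float, list[G4Region]] = {}
    tracks = {name: base_scores(seq, sequence_id=name) for name, seq in genome.items()}
    wmeans = {name: window_scores(tr, params) for name, tr in tracks.items()}
    for t in ts:
        hits: list[G4Region] = []
        for name, seq in genome.items():
            hits.extend(_hits_from_windows(seq, name, wmeans[name], params, t))
        out[t] = hits
    return out


def _hits_from_windows(seq, name, wmeans, params, threshold):
    # shares merge logic with find_hits but reuses precomputed window means
    w = min(params.window_length, len(seq))
    qualifying = np.flatnonzero(np.abs(wmeans) >= threshold)
    if qualifying.size == 0:
        return []
    signs = np.sign(wmeans[qualifying]).astype(int)
    useq = seq.upper()
    regions = []
    run_start, run_end = int(qualifying[0]), int(qualifying[0]) + w
    run_sign, best = int(signs[0]), float(wmeans[qualifying[0]])
    for idx, sgn in zip(qualifying[1:], signs[1:]):
        idx = int(idx)
        if sgn == run_sign and idx - run_end <= params.min_gap_to_merge:
            run_end = idx + w
            if abs(wmeans[idx]) > abs(best):
                best = float(wmeans[idx])
        else:
            regions.append(
                G4Region(name, run_start, run_end, run_sign,
                         sequence_score(useq[run_start:run_end]), best, threshold)
            )
            run_start, run_end, run_sign = idx, idx + w, int(sgn)
            best = float(wmeans[idx])
    regions.append(
        G4Region(name, run_start, run_end, run_sign,
                 sequence_score(useq[run_start:run_end]), best, threshold)
    )
    return regions


def write_regions(regions: list[G4Region], path: str | Path, format: str = "TSV") -> None:
    """Write regions as BED6 or full-precision TSV.

    BED score column is ``clamp(|region_score| * 250, 0, 1000)`` rounded,
    name is ``chrom:start-end`` and strand encodes the sign.
    """
    path = Path(path)
    fmt = format.upper()
    if fmt == "BED":
        with path.open("w") as fh:
            for r in regions:
                bed_score = int(round(min(max(abs(r.region_score) * 250.0, 0.0), 1000.0)))
                strand = "+" if r.sign > 0 else "-"
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.chrom}:{r.start}-{r.end}"
                    f"\t{bed_score}\t{strand}\n"
                )
    elif fmt == "TSV":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(_TSV_FIELDS)
            for r in regions:
                writer.writerow(
                    [r.chrom, r.start, r.end, r.sign,
                     repr(r.region_score), repr(r.max_window_score), repr(r.threshold)]
                )
    else:
        raise ValueError(f"unknown format {format!r} (expected BED or TSV)")


def read_regions(path: str | Path) -> list[G4Region]:
    """Read back a TSV written by :func:`write_regions` (exact round-trip)."""
    regions = []
    with Path(path).open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            regions.append(
                G4Region(
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    sign=int(row["sign"]),
                    region_score=float(row["region_score"]),
                    max_window_score=float(row["max_window_score"]),
                    threshold=float(row["threshold"]),
                )
            )
    return regions
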
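"""Feature-class enrichment and distributional statistics for G4 scans.

Produces the per-feature count/density/relative-density table, the fraction
of promoters carrying at least one hit, the strand orientation of intronic
hits relative to their host gene, per-chromosome density tests, and a
two-regime log-linear fit of genome density against calling threshold.

Counting is strand-agnostic: a region overlapping a feature class by one or
more bases counts once for that class regardless of strand, and a region may
be counted in several (overlapping) classes.  Densities are hits per kb of
the class's union length; relative density divides by the whole-genome
density at the same threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import FeatureSet
from .intervals import MergedIntervals
from .regions import G4Region

__all__ = [
    "EnrichmentRow",
    "ThresholdDensityFit",
    "ChromTestResult",
    "overlap_counts",
    "enrichment_table",
    "enrichment_frame",
    "promoter_hit_fraction",
    "intron_strand_bias",
    "chromosome_density_test",
    "fit_threshold_density",
]


@dataclass(frozen=True)
class EnrichmentRow:
    """One feature x threshold cell of the enrichment table."""

    feature_name: str
    threshold: float
    n_hits: int
    feature_length_kb: float
    density: float  # hits per kb
    relative_density: float  # density / whole-genome density


@dataclass(frozen=True)
class ThresholdDensityFit:
    """Two-regime OLS fit of log10(density) against threshold."""

    breakpoint: float
    slope_low: float
    intercept_low: float
    slope_high: float
    intercept_high: float


@dataclass(frozen=True)
class ChromTestResult:
    chrom: str
    n_hits: int
    chrom_length: int
    observed_density: float  # hits per kb
    p_value: float
    p_adjusted: float
    method: str


def _check_chrom_names(regions: Sequence[G4Region], features: FeatureSet) -> None:
    region_chroms = {r.chrom for r in regions}
    feature_chroms = {iv[0] for iv in features.intervals}
    missing = region_chroms - feature_chroms
    # regions on chromosomes entirely absent from the union are legitimate
    # (a class need not cover every chromosome), so only flag the fully
    # disjoint case, which almost always means mismatched naming schemes
    if regions and features.intervals and not (region_chroms & feature_chroms):
        raise ValueError(
            "no chromosome name shared between regions and feature set "
            f"{features.name!r}: regions use {sorted(region_chroms)[:5]}, "
            f"features use {sorted(feature_chroms)[:5]}"
        )
    del missing


def overlap_counts(regions: Sequence[G4Region], features: FeatureSet) -> int:
    """Number of regions overlapping the feature union by >= 1 bp.

    Each region counts at most once per feature class; strand is ignored.
    """
    _check_chrom_names(regions, features)
    merged = MergedIntervals((c, s, e) for c, s, e, _ in features.intervals)
    return sum(merged.overlaps(r.chrom, r.start, r.end) for r in regions)


def enrichment_table(
    hits_by_threshold: Mapping[float, Sequence[G4Region]],
    feature_sets: Mapping[str, FeatureSet],
) -> list[EnrichmentRow]:
    """Count/density/relative-density rows for every feature x threshold.

    *feature_sets* must contain a ``WholeGenome`` entry; relative densities
    are normalised against it per threshold.  A zero-length feature class is
    an error (its density is undefined).
    """
    if "WholeGenome" not in feature_sets:
        raise ValueError("feature_sets must include a WholeGenome entry")
    for name, fs in feature_sets.items():
        if fs.total_length == 0:
            raise ValueError(f"feature class {name!r} has zero union length")
    rows: list[EnrichmentRow] = []
    for threshold in sorted(hits_by_threshold):
        regions = hits_by_threshold[threshold]
        wg = feature_sets["WholeGenome"]
        wg_density = overlap_counts(regions, wg) / (wg.total_length / 1000.0)
        for name, fs in feature_sets.items():
            n = overlap_counts(regions, fs)
            length_kb = fs.total_length / 1000.0
            density = n / length_kb
            rel = density / wg_density if wg_density > 0 else float("nan")
            rows.append(
                EnrichmentRow(
                    feature_name=name, threshold=threshold, n_hits=n,
                    feature_length_kb=length_kb, density=density,
                    relative_density=rel,
                )
            )
    return rows


def enrichment_frame(rows: Iterable[EnrichmentRow]) -> pd.DataFrame:
    """Enrichment rows as a tidy DataFrame (one row per feature x threshold)."""
    return pd.DataFrame(
        [
            {
                "feature": r.feature_name,
                "threshold": r.threshold,
                "n": r.n_hits,
                "length_kb": r.feature_length_kb,
                "density": r.density,
                "relative_density": r.relative_density,
            }
            for r in rows
        ]
    )


def promoter_hit_fraction(
    promoters: FeatureSet, regions: Sequence[G4Region]
) -> float:
    """Fraction of individual promoter windows overlapping >= 1 region.

    Overlapping promoters of adjacent genes count separately here (the
    denominator is the number of promoter windows, not their union length).
    """
    if not promoters.intervals:
        raise ValueError("empty promoter set")
    if not regions:
        return 0.0
    merged = MergedIntervals((r.chrom, r.start, r.end) for r in regions)
    hit = sum(
        merged.overlaps(chrom, s, e) for chrom, s, e, _ in promoters.intervals
    )
    return hit / len(promoters.intervals)


def intron_strand_bias(
    regions: Sequence[G4Region], introns: FeatureSet
) -> dict[str, int]:
    """Orientation of intronic hits relative to the host gene.

    A +1 (G-rich forward) hit in a + strand gene's intron sits on the coding
    strand — the intron's mRNA copy is G-rich; the mirrored combinations put
    the quadruplex on the template strand (C-rich mRNA intron).  A hit
    overlapping introns of both gene strands increments both counters and
    the ambiguity tally.
    """
    plus = MergedIntervals(
        (c, s, e) for c, s, e, strand in introns.intervals if strand == "+"
    )
    minus = MergedIntervals(
        (c, s, e) for c, s, e, strand in introns.intervals if strand == "-"
    )
    counts = {"coding_strand_G4": 0, "template_strand_G4": 0, "ambiguous": 0}
    for r in regions:
        in_plus = plus.overlaps(r.chrom, r.start, r.end)
        in_minus = minus.overlaps(r.chrom, r.start, r.end)
        if in_plus and in_minus:
            counts["ambiguous"] += 1
        if in_plus:
            key = "coding_strand_G4" if r.sign > 0 else "template_strand_G4"
            counts[key] += 1
        if in_minus:
            key = "coding_strand_G4" if r.sign < 0 else "template_strand_G4"
            counts[key] += 1
    return counts


def chromosome_density_test(
    regions: Sequence[G4Region],
    chrom_lengths: Mapping[str, int],
    method: str = "binomial",
    n_permutations: int = 10000,
    seed: int | None = None,
) -> list[ChromTestResult]:
    """Per-chromosome test of uniform hit placement across the genome.

    H0: each hit falls on a given chromosome with probability proportional
    to its length.  ``binomial`` uses the exact two-sided binomial test;
    ``permutation`` redraws every hit's chromosome from the length
    distribution *n_permutations* times (seeded) and reports a two-sided
    empirical p-value.  p-values are Benjamini-Hochberg adjusted across
    chromosomes.
    """
    if len(chrom_lengths) < 2:
        raise ValueError("need >= 2 chromosomes")
    total_hits = len(regions)
    if total_hits == 0:
        raise ValueError("no hits to test")
    genome_len = sum(chrom_lengths.values())
    counts = {c: 0 for c in chrom_lengths}
    for r in regions:
        if r.chrom in counts:
            counts[r.chrom] += 1

    chroms = list(chrom_lengths)
    pvals: list[float] = []
    if method == "binomial":
        for c in chroms:
            p0 = chrom_lengths[c] / genome_len
            res = stats.binomtest(counts[c], total_hits, p0, alternative="two-sided")
            pvals.append(res.pvalue)
    elif method == "permutation":
        if n_permutations < 1000:
            raise ValueError("n_permutations must be >= 1000")
        rng = np.random.default_rng(seed)
        probs = np.array([chrom_lengths[c] / genome_len for c in chroms])
        sim = rng.multinomial(total_hits, probs, size=n_permutations)
        obs = np.array([counts[c] for c in chroms])
        expected = total_hits * probs
        # two-sided: permuted count at least as far from expectation
        dev_obs = np.abs(obs - expected)
        dev_sim = np.abs(sim - expected)
        pvals = [
            float((np.sum(dev_sim[:, i] >= dev_obs[i]) + 1) / (n_permutations + 1))
            for i in range(len(chroms))
        ]
    else:
        raise ValueError(f"unknown method {method!r}")

    adjusted = multipletests(pvals, method="fdr_bh")[1]
    return [
        ChromTestResult(
            chrom=c,
            n_hits=counts[c],
            chrom_length=chrom_lengths[c],
            observed_density=counts[c] / (chrom_lengths[c] / 1000.0),
            p_value=float(p),
            p_adjusted=float(pa),
            method=method,
        )
        for c, p, pa in zip(chroms, pvals, adjusted)
    ]


def fit_threshold_density(
    thresholds: Sequence[float],
    densities: Sequence[float],
    breakpoint: float = 1.4,
) -> ThresholdDensityFit:
    """Fit log10(density) ~ threshold separately below and above a breakpoint.

    Genome-wide G4 density falls roughly exponentially with the calling
    threshold; AT-rich unicellular genomes show a steeper decay at low
    thresholds than at high ones, so the fit uses two regimes split at a
    user-supplied breakpoint (not an estimated changepoint).  Points at or
    below the breakpoint belong to the low regime; each regime needs >= 2
    points and all densities must be positive.
    """
    t = np.asarray(thresholds, dtype=float)
    d = np.asarray(densities, dtype=float)
    if t.shape != d.shape:
        raise ValueError("thresholds and densities must have equal length")
    if np.any(d <= 0):
        raise ValueError("densities must be positive (log fit)")
    low = t <= breakpoint
    high = ~low
    if low.sum() < 2 or high.sum() < 2:
        raise ValueError(
            f"need >= 2 points per regime around breakpoint {breakpoint} "
            f"(got {int(low.sum())} low, {int(high.sum())} high)"
        )
    slope_low, intercept_low = np.polyfit(t[low], np.log10(d[low]), 1)
    slope_high, intercept_high = np.polyfit(t[high], np.log10(d[high]), 1)
    return ThresholdDensityFit(
        breakpoint=breakpoint,
        slope_low=float(slope_low),
        intercept_low=float(intercept_low),
        slope_high=float(slope_high),
        intercept_high=float(intercept_high),
    )
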
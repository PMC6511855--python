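"""Enrichment counting, promoter fractions, strand bias, chromosome tests
and the two-regime threshold-density fit."""

import numpy as np
import pytest

from g4map.enrichment import (
    chromosome_density_test,
    enrichment_table,
    fit_threshold_density,
    intron_strand_bias,
    overlap_counts,
    promoter_hit_fraction,
)
from g4map.features import FeatureSet
from g4map.regions import G4Region


def _region(chrom, start, end, sign=1, threshold=1.5):
    return G4Region(chrom, start, end, sign, 2.0 * sign, 2.0 * sign, threshold)


def test_overlap_counts_basics():
    fs = FeatureSet("f", [("chr1", 0, 1000, "+")])
    assert overlap_counts([_region("chr1", 100, 130)], fs) == 1
    # a region spanning two promoter windows of one class counts once
    fs2 = FeatureSet("f", [("chr1", 0, 110, "+"), ("chr1", 120, 300, "+")])
    assert overlap_counts([_region("chr1", 100, 130)], fs2) == 1
    # bookended (zero-bp overlap) does not count
    assert overlap_counts([_region("chr1", 300, 330)], fs2) == 0


def test_overlap_counts_chrom_mismatch():
    fs = FeatureSet("f", [("1", 0, 1000, "+")])
    with pytest.raises(ValueError, match="chromosome name"):
        overlap_counts([_region("chr1", 0, 30)], fs)


def test_overlap_counts_matches_brute_force_oracle():
    rng = np.random.default_rng(4)
    chroms = ["chr1", "chr2", "chr3"]
    regions = [
        _region(chroms[rng.integers(3)], s := int(rng.integers(0, 9_970)), s + 30)
        for _ in range(200)
    ]
    intervals = [
        (chroms[rng.integers(3)], s := int(rng.integers(0, 9_900)),
         s + int(rng.integers(10, 100)), "+")
        for _ in range(100)
    ]
    fs = FeatureSet("rand", intervals)
    brute = sum(
        any(r.chrom == c and r.start < e and s < r.end for c, s, e, _ in intervals)
        for r in regions
    )
    assert overlap_counts(regions, fs) == brute


def test_enrichment_table_relative_densities():
    fsets = {
        "WholeGenome": FeatureSet("WholeGenome", [("chr1", 0, 10_000, ".")]),
        "feat": FeatureSet("feat", [("chr1", 0, 1000, "+")]),
    }
    hits = {1.5: [_region("chr1", 10, 40), _region("chr1", 500, 530)]}
    rows = {r.feature_name: r for r in enrichment_table(hits, fsets)}
    assert rows["feat"].n_hits == 2
    assert rows["feat"].density == pytest.approx(2.0)  # 2 hits / 1 kb
    assert rows["WholeGenome"].relative_density == pytest.approx(1.0)
    assert rows["feat"].relative_density == pytest.approx(10.0)


def test_enrichment_table_zero_length_feature_errors():
    fsets = {
        "WholeGenome": FeatureSet("WholeGenome", [("chr1", 0, 10_000, ".")]),
        "bad": FeatureSet("bad", []),
    }
    with pytest.raises(ValueError, match="zero union length"):
        enrichment_table({1.5: []}, fsets)


def test_promoter_hit_fraction():
    proms = FeatureSet(
        "Prom500", [("chr1", i * 1000, i * 1000 + 500, "+") for i in range(10)]
    )
    assert promoter_hit_fraction(proms, [_region("chr1", 100, 130)]) == 0.1
    assert promoter_hit_fraction(proms, []) == 0.0
    with pytest.raises(ValueError):
        promoter_hit_fraction(FeatureSet("empty", []), [])


def test_intron_strand_bias_definition():
    introns = FeatureSet(
        "Introns", [("chr1", 0, 1000, "+"), ("chr1", 2000, 3000, "-")]
    )
    counts = intron_strand_bias([_region("chr1", 100, 130, sign=-1)], introns)
    assert counts == {"coding_strand_G4": 0, "template_strand_G4": 1, "ambiguous": 0}
    counts = intron_strand_bias([_region("chr1", 2100, 2130, sign=-1)], introns)
    assert counts == {"coding_strand_G4": 1, "template_strand_G4": 0, "ambiguous": 0}
    # a hit under introns of both strands increments both and the tally
    both = FeatureSet(
        "Introns", [("chr1", 0, 1000, "+"), ("chr1", 500, 1500, "-")]
    )
    counts = intron_strand_bias([_region("chr1", 600, 630, sign=1)], both)
    assert counts["ambiguous"] == 1
    assert counts["coding_strand_G4"] == 1 and counts["template_strand_G4"] == 1


def test_planted_c_rich_intron_motifs_are_template_strand(planted_genome):
    """C-rich motifs planted in introns land on the template strand of
    + genes and the coding strand of - genes."""
    import g4map

    gn = planted_genome
    intron_truth = gn.truth[gn.truth.feature_class == "intron"]
    assert len(intron_truth) == 3
    hits = []
    from g4map.scoring import ScanParams

    for name, seq in gn.sequences.items():
        hits.extend(g4map.find_hits(seq, name, ScanParams(), 2.0))
    # restrict to hits overlapping planted intron motifs
    intronic = [
        r
        for r in hits
        if any(
            r.chrom == row.chrom and r.start < row.end and row.start < r.end
            for row in intron_truth.itertuples()
        )
    ]
    assert len(intronic) == 3
    assert all(r.sign == -1 for r in intronic)  # planted as reverse-strand G4
    gene_strand = {}
    for row in intron_truth.itertuples():
        for g in gn.gene_models:
            if g["chrom"] == row.chrom and g["start"] <= row.start < g["end"]:
                gene_strand[(row.chrom, row.start)] = g["strand"]
    expected_template = sum(1 for s in gene_strand.values() if s == "+")
    intron_ivs = []
    for g in gn.gene_models:
        for (_, e1), (s2, _) in zip(g["exons"], g["exons"][1:]):
            intron_ivs.append((g["chrom"], e1, s2, g["strand"]))
    introns_fs = FeatureSet("Introns", intron_ivs)
    counts = intron_strand_bias(intronic, introns_fs)
    assert counts["template_strand_G4"] == expected_template
    assert counts["coding_strand_G4"] == 3 - expected_template


def test_chromosome_test_uniform_and_biased():
    lengths = {"chr1": 100_000, "chr2": 100_000, "chr3": 100_000, "chr4": 100_000}
    # exactly proportional: two-sided exact binomial p >= 0.5 everywhere
    regions = [
        _region(c, i * 100, i * 100 + 30) for c in lengths for i in range(25)
    ]
    for res in chromosome_density_test(regions, lengths):
        assert res.p_value >= 0.5
    # one chromosome at 3x the uniform rate
    biased = [_region("chr1", i * 30, i * 30 + 25) for i in range(300)] + [
        _region(c, i * 100, i * 100 + 30)
        for c in ["chr2", "chr3", "chr4"]
        for i in range(100)
    ]
    results = {r.chrom: r for r in chromosome_density_test(biased, lengths)}
    assert results["chr1"].p_value < 0.05


def test_chromosome_test_permutation_is_seeded():
    lengths = {"chr1": 50_000, "chr2": 150_000}
    regions = [_region("chr1", i * 40, i * 40 + 30) for i in range(60)] + [
        _region("chr2", i * 40, i * 40 + 30) for i in range(40)
    ]
    a = chromosome_density_test(regions, lengths, method="permutation",
                                n_permutations=2000, seed=12)
    b = chromosome_density_test(regions, lengths, method="permutation",
                                n_permutations=2000, seed=12)
    assert a == b
    assert all(0.0 < r.p_value <= 1.0 for r in a)


def test_chromosome_test_input_validation():
    lengths = {"chr1": 1000, "chr2": 1000}
    with pytest.raises(ValueError, match="no hits"):
        chromosome_density_test([], lengths)
    with pytest.raises(ValueError, match=">= 2 chromosomes"):
        chromosome_density_test([_region("chr1", 0, 30)], {"chr1": 1000})


def test_fit_threshold_density_exact_single_slope():
    ts = [1.5, 1.75, 2.0]
    ds = [10 ** (-3.0 * t) for t in ts]
    fit = fit_threshold_density(ts + [1.0, 1.2], ds + [10 ** -3.0, 10 ** -3.6],
                                breakpoint=1.4)
    assert fit.slope_high == pytest.approx(-3.0)
    assert fit.slope_low == pytest.approx(-3.0)


def test_fit_threshold_density_two_regimes_with_noise():
    rng = np.random.default_rng(8)
    low_t = np.array([1.0, 1.1, 1.2, 1.3, 1.4])
    high_t = np.array([1.5, 1.6, 1.75, 1.9, 2.0])
    low_d = 10 ** (-4.5 * low_t + 2.0 + rng.normal(0, 0.01, low_t.size))
    high_d = 10 ** (-3.0 * high_t + rng.normal(0, 0.01, high_t.size))
    fit = fit_threshold_density(
        np.concatenate([low_t, high_t]), np.concatenate([low_d, high_d]),
        breakpoint=1.4,
    )
    assert fit.slope_low == pytest.approx(-4.5, abs=0.1)
    assert fit.slope_high == pytest.approx(-3.0, abs=0.1)


def test_fit_threshold_density_errors():
    with pytest.raises(ValueError, match="positive"):
        fit_threshold_density([1.0, 1.2, 1.5, 2.0], [0.1, 0.0, 0.01, 0.001])
    with pytest.raises(ValueError, match="per regime"):
        fit_threshold_density([1.5, 1.75, 2.0], [0.1, 0.01, 0.001], breakpoint=1.4)
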
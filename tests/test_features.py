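"""GFF3 parsing, feature-class derivation and GC content."""

import numpy as np
import pytest

from g4map.features import (
    Annotation,
    FeatureSet,
    PromoterSpec,
    cds,
    exons,
    feature_sets,
    gc_content,
    intergenic,
    introns,
    load_annotation,
    promoters,
    transcripts,
)

GFF_HEADER = "##gff-version 3\n"


def _write(tmp_path, text, name="a.gff3"):
    p = tmp_path / name
    p.write_text(text)
    return p


def test_single_exon_gene(tmp_path):
    gff = GFF_HEADER + "\n".join(
        [
            "chr1\tsrc\tgene\t101\t400\t.\t+\t.\tID=g1",
            "chr1\tsrc\tmRNA\t101\t400\t.\t+\t.\tID=t1;Parent=g1",
            "chr1\tsrc\texon\t101\t400\t.\t+\t.\tID=e1;Parent=t1",
        ]
    )
    ann = load_annotation(_write(tmp_path, gff))
    assert len(ann.genes) == 1
    assert ann.n_transcripts == 1
    assert ann.genes[0].transcripts[0].exons == [(100, 400)]
    assert introns(ann).intervals == []


def test_intron_is_transcript_minus_exons(tmp_path):
    gff = GFF_HEADER + "\n".join(
        [
            "chr1\tsrc\tgene\t1\t300\t.\t+\t.\tID=g1",
            "chr1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=t1;Parent=g1",
            "chr1\tsrc\texon\t1\t100\t.\t+\t.\tID=e1;Parent=t1",
            "chr1\tsrc\texon\t201\t300\t.\t+\t.\tID=e2;Parent=t1",
        ]
    )
    ann = load_annotation(_write(tmp_path, gff))
    assert introns(ann).intervals == [("chr1", 100, 200, "+")]
    # introns and exons partition the transcript span
    t = ann.genes[0].transcripts[0]
    covered = sorted(t.exons + t.introns())
    assert covered[0][0] == t.start and covered[-1][1] == t.end
    for (s1, e1), (s2, e2) in zip(covered, covered[1:]):
        assert e1 == s2


def test_malformed_line_raises_with_line_number(tmp_path):
    gff = GFF_HEADER + "chr1\tsrc\tgene\t1\t100\n"
    with pytest.raises(ValueError, match="line 2"):
        load_annotation(_write(tmp_path, gff))


def test_empty_annotation_warns(tmp_path, caplog):
    with caplog.at_level("WARNING"):
        ann = load_annotation(_write(tmp_path, GFF_HEADER))
    assert ann.genes == []
    assert any("no feature" in r.message for r in caplog.records)


def test_chromosome_whitelist_drops_unplaced(tmp_path):
    gff = GFF_HEADER + "\n".join(
        [
            "chr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1",
            "scaffold_7\tsrc\tgene\t1\t100\t.\t+\t.\tID=g2",
        ]
    )
    ann = load_annotation(_write(tmp_path, gff), chrom_whitelist=["chr1"])
    assert [g.gene_id for g in ann.genes] == ["g1"]


def test_gzip_input(tmp_path):
    import gzip

    gff = GFF_HEADER + "chr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1\n"
    p = tmp_path / "a.gff3.gz"
    with gzip.open(p, "wt") as fh:
        fh.write(gff)
    assert len(load_annotation(p).genes) == 1


@pytest.mark.parametrize(
    "strand,gene_start,gene_end,L,expected",
    [
        # + strand gene with 1-based TSS 1001 -> promoter 1-based 501..1000
        ("+", 1000, 2000, 500, (500, 1000)),
        # - strand gene ending 1-based 1000 -> promoter 1-based 1001..1500
        ("-", 500, 1000, 500, (1000, 1500)),
        # + strand gene near the chromosome start: clipped at 0
        ("+", 199, 1000, 500, (0, 199)),
    ],
)
def test_promoter_conventions(strand, gene_start, gene_end, L, expected):
    from g4map.features import Gene, Transcript

    tx = Transcript("t1", "chr1", gene_start, gene_end, strand, [(gene_start, gene_end)], [])
    ann = Annotation(genes=[Gene("g1", "chr1", gene_start, gene_end, strand, [tx])])
    fs = promoters(ann, PromoterSpec(L), {"chr1": 10_000})
    assert fs.intervals == [("chr1", *expected, strand)]


def test_intergenic_complements_transcripts(tmp_path):
    gff = GFF_HEADER + "\n".join(
        [
            "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1",
            "chr1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=t1;Parent=g1",
            "chr1\tsrc\texon\t101\t200\t.\t+\t.\tID=e1;Parent=t1",
        ]
    )
    ann = load_annotation(_write(tmp_path, gff))
    fs = intergenic(ann, {"chr1": 1000, "chr2": 400})
    assert ("chr1", 0, 100, ".") in fs.intervals
    assert ("chr1", 200, 1000, ".") in fs.intervals
    assert ("chr2", 0, 400, ".") in fs.intervals  # gene-free chromosome
    # conservation: intergenic + merged transcript length = genome length
    assert fs.total_length + transcripts(ann).total_length == 1400


def test_union_length_ignores_duplicates_and_order():
    ivs = [("chr1", 0, 100, "+"), ("chr1", 50, 150, "+"), ("chr1", 0, 100, "+")]
    assert FeatureSet("x", ivs).total_length == 150
    assert FeatureSet("x", list(reversed(ivs))).total_length == 150


def test_feature_sets_from_synthetic_truth(annotated_genome):
    """Generator gene/exon/intron counts round-trip through the GFF3 parser."""
    gn = annotated_genome
    ann = load_annotation_from_text(gn.gff3_text)
    assert len(ann.genes) == len(gn.gene_models)
    expected_exons = sum(len(g["exons"]) for g in gn.gene_models)
    assert sum(len(t.exons) for g in ann.genes for t in g.transcripts) == expected_exons
    expected_introns = sum(max(len(g["exons"]) - 1, 0) for g in gn.gene_models)
    assert sum(
        len(t.introns()) for g in ann.genes for t in g.transcripts
    ) == expected_introns

    fsets = feature_sets(ann, gn.chrom_lengths)
    assert set(fsets) == {
        "Prom500", "Prom1kb", "Trans", "CDS", "Exons", "Introns",
        "Intergene", "WholeGenome",
    }
    # promoters never exceed chromosome bounds
    for chrom, s, e, _ in fsets["Prom500"].intervals:
        assert 0 <= s < e <= gn.chrom_lengths[chrom]
    assert fsets["WholeGenome"].total_length == sum(gn.chrom_lengths.values())


def load_annotation_from_text(text):
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as d:
        p = Path(d) / "a.gff3"
        p.write_text(text)
        return load_annotation(p)


@pytest.mark.parametrize(
    "seq,expected",
    [("GGCC", 1.0), ("ATATGC", 1 / 3), ("ATNNAT", 0.0)],
)
def test_gc_content_sequences(seq, expected):
    assert gc_content(seq) == pytest.approx(expected)


def test_gc_content_all_n_errors():
    with pytest.raises(ValueError):
        gc_content("NNNN")


def test_gc_content_of_synthetic_background():
    """100 kb of i.i.d. background at gc=0.22 lands within the 3-sigma bound."""
    from g4map.simulate import SyntheticGenomeSpec, generate_genome

    spec = SyntheticGenomeSpec(seed=9, chrom_lengths=(100_000,), n_genes=0)
    gn = generate_genome(spec)
    assert gc_content(gn.sequences["chr1"]) == pytest.approx(0.22, abs=0.005)
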
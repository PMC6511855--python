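"""GFF3-derived genomic feature classes for enrichment analysis.

The feature classes mirror the standard promoter/transcript/CDS/exon/intron/
intergenic decomposition used for motif-density tables:

* ``Prom500`` / ``Prom1kb`` — the 500 or 1000 bp immediately upstream of each
  annotated transcription start site.  In sparsely annotated genomes (such as
  *Dictyostelium discoideum*, where UTRs are largely unannotated) the TSS
  frequently coincides with the start codon, so these windows may include
  5' UTR sequence; no UTR correction is attempted.
* ``Trans`` — merged transcript spans; ``Exons`` / ``CDS`` — merged exonic
  and coding intervals; ``Introns`` — per-transcript set difference of the
  transcript span minus its exons, deduplicated by identical coordinates.
* ``Intergene`` — the genome minus the union of transcript spans.  Promoters
  are *not* subtracted, so feature classes may overlap; density denominators
  always use the union length of each class on its own.

Coordinates are 0-based half-open internally (GFF3 input is 1-based
inclusive).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils

from .intervals import merge_intervals, union_length

__all__ = [
    "FeatureSet",
    "PromoterSpec",
    "Annotation",
    "Gene",
    "Transcript",
    "load_annotation",
    "promoters",
    "transcripts",
    "exons",
    "cds",
    "introns",
    "intergenic",
    "gc_content",
    "feature_sets",
]

logger = logging.getLogger(__name__)

Interval = tuple[str, int, int, str]  # chrom, start, end, strand


@dataclass
class FeatureSet:
    """A named collection of genomic intervals with union length."""

    name: str
    intervals: list[Interval]
    total_length: int = field(init=False)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e, _ in self.intervals:
            by_chrom.setdefault(chrom, []).append((s, e))
        self.total_length = sum(union_length(ivs) for ivs in by_chrom.values())


@dataclass(frozen=True)
class PromoterSpec:
    """Upstream promoter window anchored at the annotated TSS."""

    upstream_length: int = 500

    def __post_init__(self) -> None:
        if self.upstream_length <= 0:
            raise ValueError("upstream_length must be positive")


@dataclass
class Transcript:
    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def introns(self) -> list[tuple[int, int]]:
        """Set difference of the transcript span minus its exons."""
        if not self.exons:
            return []
        merged = merge_intervals(self.exons)
        out = []
        for (s1, e1), (s2, _) in zip(merged, merged[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out


@dataclass
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: list[Transcript]

    @property
    def tss(self) -> int:
        """0-based position of the annotated transcription start (5' end)."""
        return self.start if self.strand == "+" else self.end


@dataclass
class Annotation:
    genes: list[Gene]

    @property
    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self.genes)


def _read_gff3_text(path: str | Path) -> str:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return fh.read()


def _check_gff3_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(
                f"malformed GFF3 line {lineno}: expected 9 tab-separated "
                f"fields, got {len(fields)}"
            )


_TRANSCRIPT_TYPES = {"mRNA", "transcript"}


def load_annotation(
    gff3_path: str | Path,
    chrom_whitelist: Iterable[str] | None = None,
) -> Annotation:
    """Parse a GFF3 file into a gene -> transcript -> exon/CDS hierarchy.

    Records on sequences outside *chrom_whitelist* (when given) are dropped,
    e.g. to restrict an analysis to placed chromosomes.  Genes without an
    explicit mRNA child are modelled as one transcript; transcripts without
    exon children get a single exon covering their span.  Exons extending
    beyond their transcript are clamped with a warning.
    """
    text = _read_gff3_text(gff3_path)
    if not text.strip() or not any(
        line and not line.startswith("#") for line in text.splitlines()
    ):
        logger.warning("annotation file %s contains no feature records", gff3_path)
        return Annotation(genes=[])
    _check_gff3_lines(text)
    whitelist = set(chrom_whitelist) if chrom_whitelist is not None else None
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[Gene] = []
    for g in db.features_of_type("gene"):
        if whitelist is not None and g.seqid not in whitelist:
            continue
        gstart, gend = g.start - 1, g.end
        txs: list[Transcript] = []
        tx_feats = [
            t for t in db.children(g, level=1) if t.featuretype in _TRANSCRIPT_TYPES
        ]
        if not tx_feats:
            tx_feats = [g]  # gene without mRNA child: treat span as one transcript
        for t in tx_feats:
            tstart, tend = t.start - 1, t.end
            ex, cd = [], []
            for child in db.children(t, featuretype=("exon", "CDS")):
                cstart, cend = child.start - 1, child.end
                if cstart < tstart or cend > tend:
                    logger.warning(
                        "%s %s [%d, %d) extends beyond transcript %s; clamped",
                        child.featuretype, child.id, cstart, cend, t.id,
                    )
                    cstart, cend = max(cstart, tstart), min(cend, tend)
                (ex if child.featuretype == "exon" else cd).append((cstart, cend))
            if not ex:
                ex = [(tstart, tend)]
            txs.append(
                Transcript(
                    transcript_id=t.id, chrom=t.seqid, start=tstart, end=tend,
                    strand=t.strand, exons=sorted(ex), cds=sorted(cd),
                )
            )
        genes.append(
            Gene(gene_id=g.id, chrom=g.seqid, start=gstart, end=gend,
                 strand=g.strand, transcripts=txs)
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return Annotation(genes=genes)


def promoters(
    annotation: Annotation,
    spec: PromoterSpec,
    chrom_lengths: Mapping[str, int] | None = None,
) -> FeatureSet:
    """One upstream promoter window per gene, clipped to chromosome bounds.

    A + strand gene with TSS at 0-based t gets [t-L, t); a - strand gene
    ending at e gets [e, e+L).
    """
    L = spec.upstream_length
    out: list[Interval] = []
    for g in annotation.genes:
        if g.strand == "-":
            s, e = g.end, g.end + L
        else:
            s, e = g.start - L, g.start
        s = max(s, 0)
        if chrom_lengths is not None:
            e = min(e, chrom_lengths[g.chrom])
        if e > s:
            out.append((g.chrom, s, e, g.strand))
    name = "Prom1kb" if L == 1000 else f"Prom{L}"
    return FeatureSet(name=name, intervals=out)


def transcripts(annotation: Annotation) -> FeatureSet:
    out = [
        (t.chrom, t.start, t.end, t.strand)
        for g in annotation.genes
        for t in g.transcripts
    ]
    return FeatureSet(name="Trans", intervals=out)


def exons(annotation: Annotation) -> FeatureSet:
    out = [
        (t.chrom, s, e, t.strand)
        for g in annotation.genes
        for t in g.transcripts
        for s, e in t.exons
    ]
    return FeatureSet(name="Exons", intervals=out)


def cds(annotation: Annotation) -> FeatureSet:
    out = [
        (t.chrom, s, e, t.strand)
        for g in annotation.genes
        for t in g.transcripts
        for s, e in t.cds
    ]
    return FeatureSet(name="CDS", intervals=out)


def introns(annotation: Annotation, deduplicate: bool = True) -> FeatureSet:
    """Intron intervals across all transcripts.

    Identical coordinates shared by isoforms are counted once when
    *deduplicate* is True (the default).
    """
    raw: list[Interval] = []
    for g in annotation.genes:
        for t in g.transcripts:
            for s, e in t.introns():
                raw.append((t.chrom, s, e, t.strand))
    if deduplicate:
        raw = sorted(set(raw), key=lambda iv: (iv[0], iv[1], iv[2]))
    return FeatureSet(name="Introns", intervals=raw)


def intergenic(
    annotation: Annotation,
    chrom_lengths: Mapping[str, int],
    subtract: Iterable[FeatureSet] = (),
) -> FeatureSet:
    """Complement of the merged transcript spans over each chromosome.

    By default promoters are NOT subtracted, so promoter windows count as
    intergenic space and the two classes overlap (density tables treat each
    class independently).  Pass promoter feature sets via *subtract* for a
    strictly gene- and promoter-free complement.
    """
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for g in annotation.genes:
        for t in g.transcripts:
            spans.setdefault(t.chrom, []).append((t.start, t.end))
    for fs in subtract:
        for chrom, s, e, _ in fs.intervals:
            spans.setdefault(chrom, []).append((s, e))
    out: list[Interval] = []
    for chrom, length in chrom_lengths.items():
        merged = merge_intervals(spans.get(chrom, []))
        prev = 0
        for s, e in merged:
            if s > prev:
                out.append((chrom, prev, s, "."))
            prev = max(prev, e)
        if prev < length:
            out.append((chrom, prev, length, "."))
    return FeatureSet(name="Intergene", intervals=out)


def whole_genome(chrom_lengths: Mapping[str, int]) -> FeatureSet:
    return FeatureSet(
        name="WholeGenome",
        intervals=[(c, 0, ln, ".") for c, ln in chrom_lengths.items()],
    )


def feature_sets(
    annotation: Annotation,
    chrom_lengths: Mapping[str, int],
    promoter_lengths: Iterable[int] = (500, 1000),
) -> dict[str, FeatureSet]:
    """All standard feature classes keyed by name, including WholeGenome."""
    out: dict[str, FeatureSet] = {}
    for L in promoter_lengths:
        fs = promoters(annotation, PromoterSpec(L), chrom_lengths)
        out[fs.name] = fs
    out["Trans"] = transcripts(annotation)
    out["CDS"] = cds(annotation)
    out["Exons"] = exons(annotation)
    out["Introns"] = introns(annotation)
    out["Intergene"] = intergenic(annotation, chrom_lengths)
    out["WholeGenome"] = whole_genome(chrom_lengths)
    return out


def gc_content(
    sequence_or_featureset: str | FeatureSet,
    genome: Mapping[str, str] | None = None,
) -> float:
    """GC fraction of a sequence or of a feature set's spans in a genome.

    N (and other ambiguity codes) are excluded from the denominator; a span
    containing no unambiguous base raises ``ValueError``.
    """
    if isinstance(sequence_or_featureset, FeatureSet):
        if genome is None:
            raise ValueError("genome sequences required to compute feature GC")
        gc = acgt = 0
        for chrom, s, e, _ in sequence_or_featureset.intervals:
            sub = genome[chrom][s:e].upper()
            gc += sub.count("G") + sub.count("C")
            acgt += sum(sub.count(b) for b in "ACGT")
    else:
        sub = sequence_or_featureset.upper().replace("U", "T")
        gc = sub.count("G") + sub.count("C")
        acgt = sum(sub.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("GC content undefined: no unambiguous A/C/G/T bases in span")
    return gc / acgt


def write_bed(feature_set: FeatureSet, path: str | Path) -> None:
    """Write a feature set as BED6 (name = feature-set name, score 0)."""
    with Path(path).open("w") as fh:
        for i, (chrom, s, e, strand) in enumerate(feature_set.intervals):
            bed_strand = strand if strand in "+-" else "."
            fh.write(f"{chrom}\t{s}\t{e}\t{feature_set.name}_{i}\t0\t{bed_strand}\n")
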
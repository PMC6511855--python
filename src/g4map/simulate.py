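"""Synthetic AT-rich genomes with annotation and planted G4 motifs.

The generator emulates the salient statistics of a compact AT-rich amoebozoan
genome at desk scale: a few chromosomes of i.i.d. background sequence at a
configurable GC fraction (default 0.22, i.e. 78% AT), non-overlapping gene
models with exons and introns, upstream promoter space, and G-rich or C-rich
motifs overwritten at recorded positions.  Every output (FASTA, GFF3, truth
table) is a pure function of the spec, so identical seeds give byte-identical
files.

The truth table records, for every planted motif, its coordinates, strand,
feature class and the full-length G4Hunter score of the forward-strand
genomic subsequence — the quantity a scanner must rediscover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import merge_intervals
from .regions import G4Region, find_hits
from .scoring import ScanParams, reverse_complement, sequence_score

__all__ = [
    "PlantedMotif",
    "SyntheticGenomeSpec",
    "SyntheticGenome",
    "generate_genome",
    "strong_g4_motifs",
    "background_hit_rate",
    "recovery_report",
]

_BASES = np.array(list("ACGT"))

FeatureClass = Literal["promoter", "intron", "exon", "intergenic"]


@dataclass(frozen=True)
class PlantedMotif:
    """One motif to overwrite into the background.

    Either an explicit (chrom, position) or a feature_class target; with a
    class target the generator picks a fitting span of that class using the
    spec's seed.  Strand "-" plants the reverse complement, so a G-rich
    motif string becomes a C-rich forward-strand locus.
    """

    sequence: str
    chrom: str | None = None
    position: int | None = None
    feature_class: FeatureClass | None = None
    strand: str = "+"

    def __post_init__(self) -> None:
        if (self.chrom is None) != (self.position is None):
            raise ValueError("chrom and position must be given together")
        if self.chrom is None and self.feature_class is None:
            raise ValueError("need an explicit position or a feature_class")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Full recipe for one synthetic genome."""

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (300_000, 200_000, 100_000)
    gc_background: float = 0.22
    n_genes: int = 60
    exon_count_range: tuple[int, int] = (1, 4)
    exon_length_range: tuple[int, int] = (200, 800)
    intron_length_range: tuple[int, int] = (60, 300)
    promoter_clearance: int = 1000
    planted_motifs: tuple[PlantedMotif, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_background < 1.0):
            raise ValueError("gc_background must be in [0, 1)")
        if self.promoter_clearance < 0:
            raise ValueError("promoter_clearance must be >= 0")


@dataclass
class SyntheticGenome:
    """Generated genome bundle: sequences, annotation text and truth table."""

    spec: SyntheticGenomeSpec
    sequences: dict[str, str]
    gff3_text: str
    truth: pd.DataFrame  # motif_id, chrom, start, end, strand, score, feature_class
    gene_models: list[dict]

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with Path(path).open("w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_gff3(self, path: str | Path) -> None:
        Path(path).write_text(self.gff3_text)

    def write_truth_tsv(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)

    def write_truth_bed(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for row in self.truth.itertuples():
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t{row.motif_id}\t0\t{row.strand}\n"
                )

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}


def strong_g4_motifs(
    n: int, rng: np.random.Generator, min_score: float = 2.2
) -> list[str]:
    """Generate *n* G-rich motifs whose full-length score is >= min_score.

    Motifs are chains of 4-6 G-runs of length 4-6 joined by 1-2 nt A/T
    loops; every base of a capped run scores 4, so the mean comfortably
    clears 2.2 and a 25 nt window centred on the motif does too.
    """
    motifs = []
    while len(motifs) < n:
        n_runs = int(rng.integers(4, 7))
        parts = []
        for i in range(n_runs):
            parts.append("G" * int(rng.integers(4, 7)))
            if i < n_runs - 1:
                loop_len = int(rng.integers(1, 3))
                parts.append("".join(rng.choice(["A", "T"], size=loop_len)))
        motif = "".join(parts)
        if sequence_score(motif) >= min_score and len(motif) >= 25:
            motifs.append(motif)
    return motifs


def _draw_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def _place_genes(
    rng: np.random.Generator, spec: SyntheticGenomeSpec, chrom_names: Sequence[str]
) -> list[dict]:
    """Greedy non-overlapping gene placement with promoter clearance."""
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    lengths = dict(zip(chrom_names, spec.chrom_lengths))
    total = sum(spec.chrom_lengths)
    probs = np.array([lengths[c] / total for c in chrom_names])
    genes: list[dict] = []
    for gi in range(spec.n_genes):
        n_exons = int(rng.integers(spec.exon_count_range[0], spec.exon_count_range[1] + 1))
        exon_lens = rng.integers(
            spec.exon_length_range[0], spec.exon_length_range[1] + 1, size=n_exons
        )
        intron_lens = rng.integers(
            spec.intron_length_range[0], spec.intron_length_range[1] + 1,
            size=max(n_exons - 1, 0),
        )
        gene_len = int(exon_lens.sum() + intron_lens.sum())
        strand = "+" if rng.random() < 0.5 else "-"
        placed = False
        for _attempt in range(200):
            chrom = str(chrom_names[rng.choice(len(chrom_names), p=probs)])
            clen = lengths[chrom]
            footprint = gene_len + spec.promoter_clearance
            if footprint + 1 >= clen:
                continue
            pos = int(rng.integers(spec.promoter_clearance, clen - gene_len))
            lo, hi = pos - spec.promoter_clearance, pos + gene_len + spec.promoter_clearance
            if any(s < hi and lo < e for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((lo, hi))
            exons = []
            cursor = pos
            for k in range(n_exons):
                exons.append((cursor, cursor + int(exon_lens[k])))
                cursor += int(exon_lens[k])
                if k < n_exons - 1:
                    cursor += int(intron_lens[k])
            genes.append(
                {
                    "gene_id": f"gene{gi:04d}",
                    "chrom": chrom,
                    "start": pos,
                    "end": pos + gene_len,
                    "strand": strand,
                    "exons": exons,
                }
            )
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place gene {gi} without overlap; "
                "reduce n_genes or enlarge chromosomes"
            )
    genes.sort(key=lambda g: (g["chrom"], g["start"]))
    return genes


def _gene_introns(gene: dict) -> list[tuple[int, int]]:
    exs = gene["exons"]
    return [(e1, s2) for (_, e1), (s2, _) in zip(exs, exs[1:])]


def _promoter_span(gene: dict, clearance: int, clen: int) -> tuple[int, int]:
    if gene["strand"] == "+":
        return max(gene["start"] - clearance, 0), gene["start"]
    return gene["end"], min(gene["end"] + clearance, clen)


def _candidate_spans(
    cls: str, genes: list[dict], lengths: Mapping[str, int], clearance: int
) -> list[tuple[str, int, int]]:
    if cls == "promoter":
        return [
            (g["chrom"], *_promoter_span(g, clearance, lengths[g["chrom"]]))
            for g in genes
        ]
    if cls == "exon":
        return [(g["chrom"], s, e) for g in genes for s, e in g["exons"]]
    if cls == "intron":
        return [(g["chrom"], s, e) for g in genes for s, e in _gene_introns(g)]
    if cls == "intergenic":
        spans = []
        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in lengths}
        for g in genes:
            lo, hi = _promoter_span(g, clearance, lengths[g["chrom"]])
            occupied[g["chrom"]].append((min(lo, g["start"]), max(hi, g["end"])))
        for chrom, length in lengths.items():
            prev = 0
            for s, e in merge_intervals(occupied[chrom]):
                if s > prev:
                    spans.append((chrom, prev, s))
                prev = max(prev, e)
            if prev < length:
                spans.append((chrom, prev, length))
        return spans
    raise ValueError(f"unknown feature class {cls!r}")


def _classify(pos_chrom: str, start: int, end: int, genes: list[dict],
              lengths: Mapping[str, int], clearance: int) -> str:
    for cls in ("intron", "exon", "promoter"):
        for chrom, s, e in _candidate_spans(cls, genes, lengths, clearance):
            if chrom == pos_chrom and s < end and start < e:
                return cls
    return "intergenic"


def _gff3(genes: list[dict]) -> str:
    lines = ["##gff-version 3"]
    for g in genes:
        gid = g["gene_id"]
        attrs = f"ID={gid};Name={gid}"
        lines.append(
            f"{g['chrom']}\tg4map_sim\tgene\t{g['start'] + 1}\t{g['end']}\t.\t"
            f"{g['strand']}\t.\t{attrs}"
        )
        tid = f"{gid}.t1"
        lines.append(
            f"{g['chrom']}\tg4map_sim\tmRNA\t{g['start'] + 1}\t{g['end']}\t.\t"
            f"{g['strand']}\t.\tID={tid};Parent={gid}"
        )
        for k, (s, e) in enumerate(g["exons"]):
            lines.append(
                f"{g['chrom']}\tg4map_sim\texon\t{s + 1}\t{e}\t.\t{g['strand']}\t.\t"
                f"ID={tid}.exon{k};Parent={tid}"
            )
            lines.append(
                f"{g['chrom']}\tg4map_sim\tCDS\t{s + 1}\t{e}\t.\t{g['strand']}\t0\t"
                f"ID={tid}.cds{k};Parent={tid}"
            )
    return "\n".join(lines) + "\n"


def generate_genome(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    """Realise a spec into sequences, GFF3 annotation and a truth table.

    Raises ``ValueError`` when a planted motif collides with another motif
    or does not fit inside its target span.
    """
    rng = np.random.default_rng(spec.seed)
    chrom_names = [f"chr{i + 1}" for i in range(len(spec.chrom_lengths))]
    lengths = dict(zip(chrom_names, spec.chrom_lengths))

    arrays = {
        name: _draw_background(rng, length, spec.gc_background)
        for name, length in lengths.items()
    }
    genes = _place_genes(rng, spec, chrom_names) if spec.n_genes else []

    # resolve motif positions, then overwrite
    placements: list[tuple[str, int, int, PlantedMotif]] = []
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for motif in spec.planted_motifs:
        mlen = len(motif.sequence)
        if motif.chrom is not None:
            chrom, start = motif.chrom, motif.position
            if chrom not in lengths:
                raise ValueError(f"unknown chromosome {chrom!r}")
            if start + mlen > lengths[chrom]:
                raise ValueError(
                    f"motif at {chrom}:{start} (len {mlen}) exceeds chromosome"
                )
        else:
            spans = [
                (c, s, e)
                for c, s, e in _candidate_spans(
                    motif.feature_class, genes, lengths, spec.promoter_clearance
                )
                if e - s >= mlen
            ]
            if not spans:
                raise ValueError(
                    f"no {motif.feature_class} span can hold a {mlen} nt motif"
                )
            placed = False
            for _attempt in range(200):
                c, s, e = spans[int(rng.integers(len(spans)))]
                start = int(rng.integers(s, e - mlen + 1))
                if not any(a < start + mlen and start < b for a, b in taken[c]):
                    chrom, placed = c, True
                    break
            if not placed:
                raise ValueError("could not place motif without collision")
        end = start + mlen
        if any(a < end and start < b for a, b in taken[chrom]):
            raise ValueError(
                f"planted motif collision at {chrom}:{start}-{end}"
            )
        taken[chrom].append((start, end))
        placements.append((chrom, start, end, motif))

    base_index = {b: i for i, b in enumerate("ACGT")}
    for chrom, start, end, motif in placements:
        seq = motif.sequence.upper().replace("U", "T")
        if motif.strand == "-":
            seq = reverse_complement(seq)
        arrays[chrom][start:end] = [base_index[b] for b in seq]

    sequences = {name: "".join(_BASES[arr]) for name, arr in arrays.items()}

    truth_rows = []
    for i, (chrom, start, end, motif) in enumerate(placements):
        fwd = sequences[chrom][start:end]
        cls = motif.feature_class or _classify(
            chrom, start, end, genes, lengths, spec.promoter_clearance
        )
        truth_rows.append(
            {
                "motif_id": f"motif{i:03d}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": motif.strand,
                "score": sequence_score(fwd),
                "feature_class": cls,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["motif_id", "chrom", "start", "end", "strand", "score", "feature_class"],
    )
    return SyntheticGenome(
        spec=spec,
        sequences=sequences,
        gff3_text=_gff3(genes),
        truth=truth,
        gene_models=genes,
    )


def background_hit_rate(
    spec: SyntheticGenomeSpec,
    params: ScanParams,
    threshold: float,
    n_replicates: int = 5,
    seed: int = 0,
) -> dict[str, float]:
    """Monte-Carlo G4FS density (hits/kb) in motif-free background.

    Replicates regenerate the background with sub-seeds derived from *seed*;
    the CI is the normal-approximation 95% interval over replicate densities.
    """
    if n_replicates < 3:
        raise ValueError("n_replicates must be >= 3")
    densities = []
    for i in range(n_replicates):
        rep = replace(spec, seed=(seed * 1000 + i) % (2**31), planted_motifs=(), n_genes=0)
        genome = generate_genome(rep)
        n_hits = sum(
            len(find_hits(seq, name, params, threshold))
            for name, seq in genome.sequences.items()
        )
        densities.append(n_hits / (sum(rep.chrom_lengths) / 1000.0))
    arr = np.array(densities)
    half = 1.96 * arr.std(ddof=1) / np.sqrt(n_replicates)
    return {
        "density": float(arr.mean()),
        "ci_low": float(arr.mean() - half),
        "ci_high": float(arr.mean() + half),
        "n_replicates": n_replicates,
    }


def recovery_report(
    found: Sequence[G4Region], truth: pd.DataFrame
) -> dict:
    """Score found regions against the planted truth.

    A motif is recovered when a found region overlaps it by >= 1 bp with the
    matching sign (+1 for "+" planted motifs, -1 for "-").  Precision is
    None when nothing was found.
    """
    statuses = []
    n_recovered = 0
    for row in truth.itertuples():
        want_sign = 1 if row.strand == "+" else -1
        hit = any(
            r.chrom == row.chrom and r.start < row.end and row.start < r.end
            and r.sign == want_sign
            for r in found
        )
        statuses.append({"motif_id": row.motif_id, "recovered": hit})
        n_recovered += hit
    n_truth = len(truth)
    sensitivity = n_recovered / n_truth if n_truth else float("nan")
    if found:
        n_true_regions = sum(
            any(
                r.chrom == row.chrom and r.start < row.end and row.start < r.end
                for row in truth.itertuples()
            )
            for r in found
        )
        precision = n_true_regions / len(found)
    else:
        precision = None
    return {
        "sensitivity": sensitivity,
        "precision": precision,
        "n_planted": n_truth,
        "n_found": len(found),
        "per_motif": statuses,
    }
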
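"""End-to-end orchestration: genome + annotation -> enrichment report bundle.

``run_full_analysis`` reproduces the whole mapping analysis for any genome /
GFF3 pair (real or synthetic): per-threshold region calls, feature classes,
the count/density/relative-density table, promoter hit fractions, per-feature
GC content, intron strand bias, per-chromosome density tests and (threshold
sweep permitting) the two-regime density fit.  All randomness (the optional
permutation test) flows from the single config seed, and reruns with an
identical config are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from . import __version__
from .enrichment import (
    chromosome_density_test,
    enrichment_frame,
    enrichment_table,
    fit_threshold_density,
    intron_strand_bias,
    promoter_hit_fraction,
)
from .features import feature_sets, gc_content, load_annotation, write_bed
from .oligos import G4_PANEL
from .patterns import QuadparserPattern, quadparser_match
from .regions import hits_by_threshold, write_regions
from .scoring import ScanParams, format_score, sequence_score

__all__ = ["PipelineConfig", "run_full_analysis", "score_oligos", "read_genome"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genome_path: str | Path
    annotation_path: str | Path
    output_dir: str | Path
    window_length: int = 25
    thresholds: tuple[float, ...] = (1.5, 1.75, 2.0)
    promoter_lengths: tuple[int, ...] = (500, 1000)
    chrom_whitelist: tuple[str, ...] | None = None
    density_fit_breakpoint: float = 1.4
    chrom_test_method: str = "binomial"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.thresholds:
            raise ValueError("thresholds must be non-empty")
        for p in (self.genome_path, self.annotation_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def read_genome(
    path: str | Path, chrom_whitelist: Iterable[str] | None = None
) -> dict[str, str]:
    """Read a (multi-)FASTA into a name -> sequence dict, optionally filtered."""
    whitelist = set(chrom_whitelist) if chrom_whitelist is not None else None
    genome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if whitelist is None or rec.id in whitelist:
            genome[rec.id] = str(rec.seq)
    if not genome:
        raise ValueError(f"no usable sequences in {path}")
    return genome


def run_full_analysis(config: PipelineConfig) -> dict[str, Path]:
    """Run the full mapping analysis; returns a name -> path map of outputs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    params = ScanParams(
        window_length=config.window_length, thresholds=tuple(config.thresholds)
    )

    def _stage(name):
        logger.info("stage: %s", name)

    _stage("read genome")
    genome = read_genome(config.genome_path, config.chrom_whitelist)
    # chromosome order must not affect any output
    genome = dict(sorted(genome.items()))
    chrom_lengths = {name: len(seq) for name, seq in genome.items()}

    _stage("load annotation")
    annotation = load_annotation(config.annotation_path, config.chrom_whitelist)
    fsets = feature_sets(annotation, chrom_lengths, config.promoter_lengths)

    _stage("scan")
    hits = hits_by_threshold(genome, params)
    for t, regions in hits.items():
        tag = f"T{t:g}".replace(".", "p")
        bed = out / f"regions_{tag}.bed"
        tsv = out / f"regions_{tag}.tsv"
        write_regions(regions, bed, "BED")
        write_regions(regions, tsv, "TSV")
        outputs[f"regions_{tag}_bed"] = bed
        outputs[f"regions_{tag}_tsv"] = tsv
        logger.info(
            "threshold %g: %d regions (%s)", t, len(regions),
            ", ".join(
                f"{c}={sum(r.chrom == c for r in regions)}" for c in chrom_lengths
            ),
        )

    _stage("feature beds")
    for name, fs in fsets.items():
        p = out / f"feature_{name}.bed"
        write_bed(fs, p)
        outputs[f"feature_{name}"] = p

    _stage("enrichment table")
    rows = enrichment_table(hits, fsets)
    enr = enrichment_frame(rows)
    p = out / "enrichment.tsv"
    enr.to_csv(p, sep="\t", index=False)
    outputs["enrichment"] = p

    _stage("promoter hit fraction")
    frac_rows = []
    for t in sorted(hits):
        for L in config.promoter_lengths:
            name = "Prom1kb" if L == 1000 else f"Prom{L}"
            frac_rows.append(
                {
                    "promoter": name,
                    "threshold": t,
                    "fraction_with_hit": promoter_hit_fraction(fsets[name], hits[t]),
                }
            )
    p = out / "promoter_fraction.tsv"
    pd.DataFrame(frac_rows).to_csv(p, sep="\t", index=False)
    outputs["promoter_fraction"] = p

    _stage("feature GC")
    gc_rows = []
    for name, fs in fsets.items():
        try:
            gc = gc_content(fs, genome)
        except ValueError:
            gc = float("nan")
        gc_rows.append({"feature": name, "gc_fraction": gc})
    p = out / "feature_gc.tsv"
    pd.DataFrame(gc_rows).to_csv(p, sep="\t", index=False)
    outputs["feature_gc"] = p

    _stage("intron strand bias")
    bias_rows = []
    for t in sorted(hits):
        counts = intron_strand_bias(hits[t], fsets["Introns"])
        bias_rows.append({"threshold": t, **counts})
    p = out / "intron_strand_bias.tsv"
    pd.DataFrame(bias_rows).to_csv(p, sep="\t", index=False)
    outputs["intron_strand_bias"] = p

    _stage("chromosome density test")
    test_rows = []
    for t in sorted(hits):
        if len(chrom_lengths) < 2 or not hits[t]:
            logger.info("chromosome test skipped at T=%g (needs >=2 chroms and >=1 hit)", t)
            continue
        for res in chromosome_density_test(
            hits[t], chrom_lengths, method=config.chrom_test_method,
            seed=config.seed,
        ):
            test_rows.append(
                {
                    "threshold": t, "chrom": res.chrom, "n_hits": res.n_hits,
                    "chrom_length": res.chrom_length,
                    "density": res.observed_density, "p_value": res.p_value,
                    "p_adjusted": res.p_adjusted, "method": res.method,
                }
            )
    if test_rows:
        p = out / "chromosome_test.tsv"
        pd.DataFrame(test_rows).to_csv(p, sep="\t", index=False)
        outputs["chromosome_test"] = p

    _stage("threshold-density fit")
    wg = enr[enr["feature"] == "WholeGenome"].sort_values("threshold")
    bp = config.density_fit_breakpoint
    ts, ds = list(wg["threshold"]), list(wg["density"])
    usable = [(t, d) for t, d in zip(ts, ds) if d > 0]
    n_low = sum(t <= bp for t, _ in usable)
    n_high = sum(t > bp for t, _ in usable)
    if n_low >= 2 and n_high >= 2:
        fit = fit_threshold_density(
            [t for t, _ in usable], [d for _, d in usable], breakpoint=bp
        )
        p = out / "threshold_density_fit.tsv"
        pd.DataFrame(
            [
                {"regime": "low", "breakpoint": bp, "slope": fit.slope_low,
                 "intercept": fit.intercept_low},
                {"regime": "high", "breakpoint": bp, "slope": fit.slope_high,
                 "intercept": fit.intercept_high},
            ]
        ).to_csv(p, sep="\t", index=False)
        outputs["threshold_density_fit"] = p
    else:
        logger.info(
            "density fit skipped: %d low / %d high usable points around %.2f",
            n_low, n_high, bp,
        )

    _stage("run log")
    p = out / "run_log.txt"
    with p.open("w") as fh:
        fh.write(f"g4map version: {__version__}\n")
        fh.write(f"genome: {config.genome_path}\n")
        fh.write(f"annotation: {config.annotation_path}\n")
        fh.write(f"chromosomes: {', '.join(chrom_lengths)}\n")
        fh.write(f"window_length: {config.window_length}\n")
        fh.write(f"thresholds: {', '.join(map(str, config.thresholds))}\n")
        fh.write("merge_policy: same-sign overlapping/bookended windows, gap 0\n")
        fh.write(f"promoter_lengths: {', '.join(map(str, config.promoter_lengths))}\n")
        fh.write(f"chrom_test_method: {config.chrom_test_method}\n")
        fh.write(f"seed: {config.seed}\n")
        for t in sorted(hits):
            fh.write(f"hits at T={t:g}: {len(hits[t])}\n")
    outputs["run_log"] = p
    return outputs


def score_oligos(
    source: str | Path | Mapping[str, str] | None = None,
    pattern: QuadparserPattern = QuadparserPattern(),
) -> pd.DataFrame:
    """Score short sequences: id, length, G4Hunter score (2 dp), consensus flag.

    *source* is a FASTA path, a name -> sequence mapping, or None for the
    built-in validation panel.  RNA input is accepted (U maps to T).
    """
    if source is None:
        seqs: Mapping[str, str] = G4_PANEL
    elif isinstance(source, Mapping):
        seqs = source
    else:
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(source), "fasta")}
    rows = []
    for name, seq in seqs.items():
        if len(seq) > 10_000:
            raise ValueError(f"sequence {name!r} exceeds 10 kb oligo limit")
        rows.append(
            {
                "id": name,
                "length": len(seq),
                "g4hunter_score": format_score(sequence_score(seq)),
                "quadparser_match": quadparser_match(seq, pattern)[0],
            }
        )
    return pd.DataFrame(rows, columns=["id", "length", "g4hunter_score", "quadparser_match"])
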
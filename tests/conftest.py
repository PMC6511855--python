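import numpy as np
import pytest

from g4map.simulate import (
    PlantedMotif,
    SyntheticGenomeSpec,
    generate_genome,
    strong_g4_motifs,
)


@pytest.fixture(scope="session")
def annotated_genome():
    """Small two-chromosome synthetic genome with genes, no planted motifs."""
    spec = SyntheticGenomeSpec(
        seed=101,
        chrom_lengths=(80_000, 50_000),
        n_genes=20,
        exon_count_range=(1, 4),
    )
    return generate_genome(spec)


@pytest.fixture(scope="session")
def planted_genome():
    """Synthetic genome with strong G4 motifs planted in known locations."""
    rng = np.random.default_rng(77)
    seqs = strong_g4_motifs(9, rng)
    motifs = (
        tuple(PlantedMotif(m, feature_class="promoter") for m in seqs[:3])
        + tuple(PlantedMotif(m, feature_class="intron", strand="-") for m in seqs[3:6])
        + tuple(PlantedMotif(m, feature_class="intergenic") for m in seqs[6:])
    )
    spec = SyntheticGenomeSpec(
        seed=55,
        chrom_lengths=(120_000, 80_000),
        n_genes=25,
        exon_count_range=(2, 4),
        planted_motifs=motifs,
    )
    return generate_genome(spec)
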
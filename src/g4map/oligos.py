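"""The 14-oligonucleotide *D. discoideum* G4 validation panel.

Fourteen distinct G4-prone sequences from the *Dictyostelium discoideum* AX4
genome (promoters, exons and suspected UTR/ncRNA loci) that were shown by
biophysical methods to fold into quadruplexes.  They serve here as the
scoring regression panel: their full-sequence G4Hunter scores are the
published reference values the scoring module must reproduce at 2 decimals.
RNA panel members are written with U; scoring maps U to T (both score 0), so
a DNA/RNA pair shares one score.
"""

from __future__ import annotations

G4_PANEL: dict[str, str] = {
    "p16": "AGGAGAGTGGGGGTGTGTGTTTGGGTGGGT",
    "p32": "AGGATTGGGGCTGGGTGTGCGGGA",
    "p40": "TGGGGGGAAGAGGGGAGAGACAGGGGGAGGTAGG",
    "p172": "GGGGGTGGGGGTGGGGTAAGGGG",
    "p23R": "UGGGAUGGGGUGACAGUUGGGGGGAGAGGGGUAUGAUG",
    "p187": "ATGGGAGGTAGATGGTGGGTGGGTGGTGA",
    "p193": "AGGGGATGGTTAGCGGTGCGACAGGGGGGAGGAGACAGGGGGA",
    "p4": "AGGTGGGGGTGAGCAGTGTGGTGTGGGT",
    "p12": "TGGTGGTGGTAGGAAGTGGT",
    "p14": "TGGTGGAGGGGGGTGGGTGGT",
    "p5": "TGGGGTTGGATGGGTGGGT",
    "p220": "TGGGAGGTGGTATGGGAGGTGGAGGC",
    "p309": "TGGGGGGAGGTGGTGGTGGTGGTGGAT",
    "p10": "GGGGGAGGGGTACAGGGGTACAGGGG",
}

#: Published G4Hunter scores (2 dp) for the panel, used as regression values.
G4_PANEL_SCORES: dict[str, float] = {
    "p16": 1.57,
    "p32": 1.58,
    "p40": 2.06,
    "p172": 3.13,
    "p23R": 1.82,
    "p187": 1.41,
    "p193": 1.67,
    "p4": 1.46,
    "p12": 1.05,
    "p14": 2.14,
    "p5": 2.00,
    "p220": 1.42,
    "p309": 1.78,
    "p10": 2.54,
}
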
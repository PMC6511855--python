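# Methods

## The scoring model

`g4map` predicts G-quadruplex-prone sequences (G4FS) with the G4Hunter
scheme, which scores both G-richness and GC skewness. Every base inside a
maximal run of *n* consecutive guanines scores `min(n, 4)`; every base
inside a maximal run of *n* cytosines scores `-min(n, 4)`; A, T, U, N and
all other IUPAC codes score 0 (only G/C runs carry quadruplex signal; U is
treated as T so DNA and RNA versions of a sequence share one score). The
score of a sequence is the arithmetic mean of its per-base scores: +2 or
higher marks a sequence extremely likely to fold into a stable quadruplex
on the given strand, and the mirrored negative values mark quadruplexes on
the complementary strand. Scores are antisymmetric under reverse
complement and bounded in [-4, 4]; reports round to two decimals with
round-half-to-even (no regression value in the validation panel sits on a
half-way boundary, so any standard rounding rule reproduces them — one was
picked and documented).

The package carries a 14-oligonucleotide validation panel from the
*Dictyostelium discoideum* AX4 genome, each member experimentally confirmed
to fold into a quadruplex; their published G4Hunter scores (1.05–3.13) are
the frozen regression surface for the scoring rule.

## Genome scanning and region calling

Genome scans average the per-base track over a 25 nt sliding window (the
conventional G4Hunter genome-scan window). Base scores are computed once
per chromosome from maximal runs in the *full* sequence and the windows
average that global track, so a run is never truncated at a window edge;
`ScanParams(truncate_runs=True)` opts into per-window truncation, which can
shift genome-wide counts marginally. Window means are exact integer
prefix-sum differences divided by the window length, hence bit-identical to
naive per-window recomputation.

A window qualifies at threshold *T* when `|mean| >= T`. Overlapping or
bookended qualifying windows of the same sign merge into one maximal region
(`min_gap_to_merge` widens the merge gap; the default 0 merges only
touching windows); opposite signs never merge, keeping strand assignment
well defined. Each merged region records the full-sequence score of its
span (recomputed on the subsequence, so runs are truncated at region
boundaries), the strongest window mean, and the calling threshold. Merging
can dilute the region score below the threshold; the guarantee is that the
best window reaches it. No boundary refinement (trimming to the outermost
qualifying G) is applied: counts depend on region number, not exact bounds.
Chromosomes shorter than the window are scanned as a single window. Each
threshold is scanned independently — filtering a lower threshold's regions
would miscount because merging differs — and hit counts are monotone
non-increasing in threshold.

One consequence worth noting: a motif whose own score exceeds the threshold
may still be missed when it is shorter than the window and its flank is
score-free. The 21 nt human-telomere-style repeat (score 1.71) in a neutral
background tops out at a window mean of 36/25 = 1.44, below a 1.5
threshold. This is faithful to windowed scanning, not a defect.

## Feature classes

Annotation is parsed from GFF3 (gzip-aware, via `gffutils`) into a gene →
transcript → exon/CDS hierarchy; records off a supplied chromosome
whitelist are dropped, genes without an mRNA child become single-transcript
genes, and exons missing entirely default to the transcript span.
Coordinates are 0-based half-open internally; human-facing reports are
1-based inclusive.

* **Prom500 / Prom1kb** — the 500 or 1000 bp immediately upstream of each
  annotated TSS, clipped to chromosome bounds, one window per gene. In
  sparsely annotated genomes the annotated TSS frequently coincides with
  the start codon, so these windows may absorb 5' UTR sequence; no UTR
  correction is attempted.
* **Trans / Exons / CDS** — merged spans of the respective records.
* **Introns** — per transcript, the span minus its exons; identical
  coordinates shared by isoforms are deduplicated by default (togglable).
* **Intergene** — the genome minus the union of transcript spans. Promoter
  windows are *not* subtracted by default, so classes overlap and a hit may
  be counted in several classes; the `subtract` option yields a strictly
  gene-and-promoter-free complement when a disjoint control region is
  needed.

Union lengths (overlaps counted once) are the density denominators.
GC content is (G+C)/(A+C+G+T) with ambiguity codes excluded from the
denominator.

## Enrichment statistics

For every feature class and threshold the table reports the number of
regions overlapping the class union by ≥ 1 bp (strand-agnostic, once per
class), the density in hits/kb, and the relative density against the
whole-genome row (identically 1.00). The promoter-hit fraction divides the
number of promoter windows containing ≥ 1 hit by the number of windows
(overlapping windows of adjacent genes count separately).

Intronic hits are classified by orientation: a hit whose sign matches its
host gene's strand is a coding-strand quadruplex (G-rich in the mRNA), a
mismatch is a template-strand quadruplex (C-rich mRNA intron). Hits under
introns of both strands increment both counters plus an ambiguity tally.

Per-chromosome uniformity is tested against H0 "hits fall uniformly per
bp": either an exact two-sided binomial test of each chromosome's count
given its length fraction (default), or a seeded multinomial permutation
test (≥ 1000 draws, two-sided empirical p). p-values are Benjamini–Hochberg
adjusted across chromosomes. The choice of test was genuinely open — no
specific test is canonical for this check — so both are provided; exact
reproduction of any published p-value is not attempted.

Genome-wide density falls roughly exponentially with threshold; AT-rich
unicellular genomes show a steeper decay at low thresholds. The two-regime
fit runs ordinary least squares of log10(density) on threshold separately
at/below and above a *user-supplied* breakpoint (default 1.4). Estimating
the changepoint is out of scope; each regime requires ≥ 2 positive-density
points.

## Synthetic genomes

The generator emulates a compact AT-rich genome at desk scale: a few
chromosomes of i.i.d. background (default GC 0.22, i.e. 78% AT, the
composition of the *D. discoideum* genome), greedily placed non-overlapping
gene models with 1–4 exons of 200–800 bp separated by 60–300 bp introns
(short, as in compact genomes), 1 kb of motif-free promoter clearance
upstream of each gene, and planted motifs overwritten at explicit positions
or inside a requested feature class (reverse-complemented for "-" strand
plants). The truth table records coordinates, strand, feature class and
the forward-strand full-length score of every plant, recomputable from the
emitted FASTA. All outputs are pure functions of the spec; identical seeds
give byte-identical files.

What the background does **not** model: dinucleotide and higher-order
composition, repeat families, chromosome-scale composition gradients, and
annotation errors. Passing tests therefore demonstrate correctness of the
machinery (scoring, calling, interval arithmetic, counting) under a
composition-matched null — not that any particular real genome's counts
will be reproduced, which additionally depends on assembly and annotation
versions. `background_hit_rate` gives a seeded Monte-Carlo estimate of the
null hit density at a given GC for interpreting observed densities.

`strong_g4_motifs` builds plants from 4–6 capped G-runs joined by 1–2 nt
A/T loops, guaranteeing full-length scores ≥ 2.2 and length ≥ 25 nt so a
25 nt window centred on the motif clears a 2.0 threshold — recovery
sensitivity 1.0 is by construction, which is exactly what an end-to-end
pipeline check needs.

## Consensus matching

The classical quadruplex consensus (four runs of ≥ 3 G separated by 1–7 nt
loops) is matched over *maximal* G-runs: a single uninterrupted run can
never supply two tracts (no internal gap exists), while loops may contain
guanines, including whole shorter runs. The matcher chains runs left to
right with backtracking and is tested for agreement with an exhaustive
subset-enumeration oracle on 10,000 random 50-mers. Of the 14 panel
oligos, only p172 and p10 satisfy the default consensus; the other 12
escape it despite folding in vitro — the panel's standing illustration of
consensus false negatives. A C-strand mirror option covers
reverse-strand quadruplexes; it is off by default because the panel is
G-rich as written.

## Numerical and scale choices

Window sums are integer-exact; all stochastic steps (background draws,
gene placement, permutation tests) flow from explicit seeds through
`numpy.random.default_rng`. Test and validation genomes are 0.25–1 Mb —
large enough for stable composition statistics (a 100 kb background pins GC
to ±0.005 at 3σ) and planted-motif recovery, small enough to regenerate on
every run rather than ship fixtures. The full *D. discoideum* analysis is a
single `run-all` invocation away once the dictyBase FASTA and GFF3 are
downloaded; a 34 Mb genome streams through the scanner in well under a
minute per threshold.

## Known limitations

* Whether published genome-wide totals deduplicated hits across classes, or
  merged across signs, is not recoverable from a count table alone; the
  merge and deduplication conventions here are explicit and togglable, and
  alternative conventions can shift genome totals by a few units.
* Promoter windows are annotation-TSS anchored; where UTRs are unannotated
  they conflate promoter and 5' UTR.
* No folding-topology prediction: parallel/antiparallel classification
  requires spectroscopy, not sequence.
* The i.i.d. background understates clustering of G in real genomes, so
  null hit-rate estimates are a lower bound for repeat-rich sequence.
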
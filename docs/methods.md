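# Methods

This note documents the models, parameters, and numerical choices behind
`gametemeth`, and what the synthetic-data validation does and does not
establish about real data.

## Bisulfite conversion model

Every genomic cytosine carries a true methylation probability
m ∈ [0, 1]. During read emission a cytosine is observed as C with
probability m + (1 − m)·ε and as T otherwise, where ε is the conversion
failure rate (default 0.01; the plausible experimental range is roughly
0.005–0.015). Conversion outcomes are independent across sites and
fragments; PCR duplicates re-emit the *same* converted fragment, because
conversion precedes amplification. The spike-in contig (`lambda`) is
unmethylated by construction in every sample, so its pooled C:(C+T) ratio
estimates ε; the estimator is exactly binomial, and tests require
agreement within three binomial standard errors.

## Alignment

Alignment is exact-match (no mismatch budget) in three-letter space,
against two converted reference images: the forward strand with C→T
("CT" text) and with G→A ("GA" text, the reverse-complement image of the
converted bottom strand). The four bisulfite strands map as:

| bisulfite strand | query                    | text | orientation |
|------------------|--------------------------|------|-------------|
| OT               | C→T(read)                | CT   | +           |
| OB               | revcomp(C→T(read))       | GA   | −           |
| CTOB             | G→A(read)                | GA   | +           |
| CTOT             | revcomp(G→A(read))       | CT   | −           |

Directional libraries (MethylC-seq) search OT/OB; amplified libraries
(WBA-seq) search all four; PBAT searches CTOT/CTOB. A read is retained
only when exactly one verified placement exists across all searched
combinations; a read whose two conversions both align (possible for
WBA) therefore counts as multi-hit and is discarded — the strictest
reading of "mapped uniquely". Two placements are distinct when they
differ in (chromosome, start, bisulfite strand).

The index stores the sorted 64-bit codes of all 32-mers of each converted
text (2 bits per base; windows containing N are excluded) and verifies
every candidate by direct string comparison, so its output provably
equals a naive O(n·m) scan — a property the test suite checks against an
independently written scanner on 100 random genomes. Minimum usable tag
length is 32 nt, matching the shortest tags the mapping scheme accepts.
Raw PBAT reads are emitted at 52 nt and trimmed (4, 1) to 47-nt tags by
the aligner, exercising the trimming path end to end.

Because alignment is mismatch-free, sequencing errors reduce yield
silently; the simulator's default error rate is 0 accordingly, and an
optional `error_rate` exists specifically to test that reads carrying
errors drop out rather than misalign.

Filters follow the mapping rules of the underlying study design:
multi-hit tags, chrY, and tags overlapping (≥1 bp) simple-repeat,
low-complexity, or satellite intervals are removed; chrM tags are
diverted to a separate stream (mitochondrial methylation is examined
separately, not discarded); deduplication keeps the first alignment per
(chromosome, start, bisulfite strand), with deterministic input order so
"first" is reproducible. Coordinates are 0-based half-open internally and
1-based inclusive only in printed interval reports.

## Calling

Evidence is read off the original (unconverted) read: C/T at reference
cytosines for OT/OB, G/A for the complementary CTOT/CTOB strands. A read
base outside the expected pair at a reference cytosine is impossible
under exact converted-space matching, so it raises an integrity error
rather than being dropped silently. Per-strand records are lossless and
merged on demand (the two cytosines of a CpG are summed) for CpG-level
analyses; CpG methylation is simulated symmetrically, and a
Kolmogorov–Smirnov test confirms plus/minus strand distributions are
indistinguishable. A site is informative at depth ≥1 (configurable).
Percents are stored at full precision and rendered to one decimal in
reports. Coverage summaries report both the all-aligned-base mean depth
(primary) and the per-CpG call depth, since the two denominators answer
different questions.

## The synthetic-data generator

The generator defines the study conditions; its defaults are fixed and
the tests run against them.

**Genome.** Three 600-kb autosomes (≈1.9 Mb with chrM, chrY and the 20-kb
spike-in), GC content 0.42, with 75% of background CpGs removed by
transition mutation to mimic the deamination-driven CpG depletion of
mammalian genomes (background density ≈0.012 CpG/nt, matching the
~0.008/nt of the real mouse genome). 120 genes (~6.5 kb, 3 exons) with
log-normal expression levels; 120 CGIs (250–900 bp, CG planted every
6–14 nt, observed density ≥3× background) placed 40% at promoters, 35%
intragenic, 25% intergenic. CGI methylation classes follow the observed
composition of the mouse CGI universe: ≈5.8% oocyte-methylated gDMRs,
1.5% sperm-methylated gDMRs, 1.6% methylated in both gametes, small
high-in-one-only and intermediate classes, the rest unmethylated in both.
Interspersed repeats (LINE/SINE/LTR/DNA, ~23% of sequence) are mutated
copies (12% divergence) of per-family consensi, CpG-depleted like the
background so they do not create artificial CpG-dense islands; simple
repeats, low-complexity runs and satellites are tandem arrays, the
satellite unit repeated verbatim genome-wide so it is multi-mapping by
construction. CGIs hold a far larger share of all CpGs here (~30%) than
in a real genome (~10%), a deliberate enrichment that gives CGI-level
statistics power at 2 Mb; it depresses pooled global methylation relative
to the real-data values, which is why global percentages are treated as
qualitative regimes, not reproduction targets.

**Methylomes.** Per-CpG values are assigned by layered rules (gene bodies,
promoters, CGIs by class, lambda always 0):

* *oocyte*: background 0.05–0.09; gene-body level = 0.15 + 0.75·(expression
  rank percentile) + noise, giving ~10–30% methylation for bottom-quintile
  and ~60–90% for top-quintile gene bodies; TSS ± 500 bp dips to ~0.12
  regardless of expression; non-CpG cytosines at rate 0.03.
* *sperm*: a decreasing function of local CpG density — 0.88 up to
  d = 0.035, declining linearly to a floor of 0.05 by d ≈ 0.095 — so bulk
  genome sits at 80–90% while CpG-rich sequence is hypomethylated;
  promoter methylation 0.90 − 0.65·rank (negative expression coupling)
  and a weak positive gene-body coupling (+0.08·(rank − 0.5) plus
  gene-level noise). Because the planted sperm-methylated CGI classes are
  high regardless of density, the pooled density curve over d ∈ [0.05, 0.2]
  is monotone non-increasing with a >30-point total drop rather than
  strictly decreasing bin-to-bin; the tests assert exactly that.
* *dnmt3l_ko* (Dnmt3L-null oocyte): ~0.04 everywhere, CGIs included
  (maternal marks are Dnmt3L-dependent), except LINE/LTR intervals held at
  0.40 to model Dnmt3L-independent partial retroelement methylation.
* *blastocyst*: background ~0.2; gDMR CGIs follow their planted fate —
  resistant ones drawn in 0.25–0.60, sensitive ones in 0.02–0.12.
* *esc*: background ~0.7; gDMRs follow the planted ESC fate partition
  (demethylated / maintained-or-increased for resistant, remethylated /
  low-maintained for sensitive, with the observed 26%/76%/81% class
  frequencies used as planting probabilities).
* *custom*: a constant m at every cytosine, for closed-form tests.

chrM is set to the small per-sample constants characteristic of
mitochondrial DNA (4–15%). ICR-like intervals are maternal (promoter,
oocyte-methylated, resistant) and paternal (intergenic, sperm-methylated,
resistant) gDMR CGIs, mirroring where real ICRs sit.

**Reads.** Fragments start uniformly at random (no size distribution or
GC bias — only coverage statistics matter downstream); read count per
contig is depth·length/read length within one read. Read length defaults
to 76 nt (52 nt raw for PBAT). Strand choice is uniform over the
protocol's strand set, which randomizes strand-of-origin for WBA as
amplification does. A `duplicate_rate` re-emits drawn fragments verbatim;
the simulator ledgers the unique-fragment count per contig so
deduplication can be validated against it. mRNA-seq tags are exact 36-nt
transcript substrings sampled proportional to expression × transcript
length; the quantifier trims the first base and matches the remaining 35
exactly, dropping tags that match more than one gene.

**Direct call sampling.** For region-level statistics (correlations at
n = 2000 genes, histogram planting) calls are sampled directly from the
true methylome — per-site coverage Poisson(depth), C count
Binomial(n, m + (1−m)ε) — which is the exact marginal the read-level path
produces at a site, without paying for 20+ Mb of read alignment per seed.
The read-level path is itself validated end-to-end on the 2-Mb genome.

## Derived analyses

CpG density windows are centred on the queried site (the anchoring is
not otherwise determined; a symmetric window is position-independent)
and truncated windows at contig ends are renormalised by their actual
length. Density bins are 0.005 wide over (0, 0.25]; bins with fewer than
100 genomic CpGs are excluded. Density curves pool counts
(ΣC/(ΣC+ΣT)) rather than averaging per-site percents, consistent with
the pooled recalculation used for element-wise summaries; pooling makes
the call-weighted bin average exactly equal the global pooled percent, an
identity the tests assert. Histogram bins are [x, x+10) with a closed top
bin, so exactly 90% falls in the "≥90%" bin.

gDMR thresholds are inclusive (≥80 / ≤20; confirmation ≥75 / ≤25;
resistance ≥20). A CGI is informative in a sample with ≥3 covered CpGs
and ≥10 pooled calls (the notion is not otherwise pinned down; both
floors are configurable). When a CGI overlaps several feature classes
the location label takes the highest precedence class
(promoter-or-first-exon first, matching where maternal ICRs are found);
when it overlaps several genes, the expression group comes from the
highest-RPKM host. The promoter is TSS ± 500 bp: the alternative TTS
anchoring that appears in one description of the regions is treated as a
typo for the TSS, since the hypomethylated band demonstrably sits at the
TSS; the anchor is switchable in `RegionSpec`.

Metagene profiles average per-gene bin means (each bin's value is the
mean percent over its covered CpGs for that gene, then averaged over the
genes of a quintile, skipping uncovered bins) rather than pooling calls
across genes; pooling would weight genes by coverage. Quintile boundaries
split the RPKM-ranked list into five near-equal groups (sizes differ by
at most one), ties resolved by stable gene-id order. Spearman p-values
use the large-sample approximation, with significance flagged at
p < 10⁻⁹.

## Problem sizes and determinism

Default validation sizes: 1.9-Mb genome at 10× for read-level round
trips; 22–26 Mb with 2000 genes (direct call sampling) for correlation
regimes; n = 5000 synthetic CGI tables for threshold recovery. These
sizes give every assertion comfortable statistical margin while keeping
a full run in minutes on one CPU. All generators are pure functions of
(inputs, seed); the pipeline derives per-stage seeds from one root seed
via CRC-named substreams, and re-running a config reproduces
byte-identical outputs (the log records the output path and so differs
across directories).

## Limitations

The generator does not model fragment-size distributions, GC or
amplification bias beyond a duplicate rate, sequencing quality scores,
indels or structural variation, realistic chromatin-driven placement of
imprinted loci, or hydroxymethylation. Passing round-trip tests
establishes that the analysis code recovers what the generative model
encodes — formulas, thresholds, strand bookkeeping, filters — not that
real libraries satisfy the model's assumptions (uniform coverage,
independent conversion, exact reads). Real-data headline values (global
methylation levels, genome-wide gDMR counts, Table-style ICR percents)
depend on the real genome and sequencing scale and are therefore treated
as qualitative regimes the simulator reproduces, not as numerical
targets.
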
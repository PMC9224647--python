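# Methods

This note documents the models, rules, and numerical choices behind
`panelsplice`, and what the synthetic cohorts do and do not establish about
real data.

## Setting and assumptions

The pipeline targets bulk RNA-seq of a targeted enrichment panel (~260 immune
genes in the motivating design; ~20 in the desk-scale synthetic cohorts) from
peripheral blood, sequenced deeply enough that individual splice junctions
carry hundreds of non-duplicate uniquely mapped reads. Three assumptions are
load-bearing:

1. **Counts are trustworthy only after duplicate and multimapper removal.**
   Junction support uses exclusively the unique-read column of `SJ.out.tab`;
   duplicate removal is an upstream contract, not re-done here. Pseudogene
   homology (e.g. NCF1/NCF1B) is explicitly out of scope — such events cannot
   be resolved from short-read RNA alone.
2. **The annotation defines normality.** "Aberrant" means relative to the
   panel junction catalog (all transcripts of the panel genes, not only
   canonical ones) and to the rest of the cohort.
3. **The cohort is the control.** There is no external reference dataset;
   usage ratios and outlier z-scores are computed against the other 12
   samples. This makes cohort size and homogeneity part of the method:
   with 13 samples a median/MAD statistic is usable but noisy, which is why
   every outlier rule pairs a z-threshold with a magnitude threshold.

## Coordinates and annotation model

All intervals are 1-based and closed, matching GTF and STAR's `SJ.out.tab`;
intron coordinates are the first and last intronic base. Overlapping exons of
a gene's transcripts are flattened into disjoint bins whose boundaries fall
exactly at the distinct exon start/end coordinates (the DEXSeq collapsing
scheme), so exon counts are unambiguous and flattening is idempotent. The
junction catalog keys introns by `(chrom, start, end, strand)`; junctions
reported with STAR strand code 0 are matched strand-agnostically, since STAR
may emit undefined strand for low-count junctions even in stranded libraries.
A junction is assigned to the gene whose span contains both splice sites;
ties between overlapping genes go to the gene sharing more annotated splice
sites, then to the lexicographically smaller symbol.

The last coding exon of a transcript is taken from CDS features; when a
transcript has no CDS the final exon in transcript orientation is used and
flagged low-confidence.

## Junction-level event detection

Two nested filters reproduce clinical-grade triage of unannotated junctions:
a per-sample pre-filter at 5 reads (mirroring the alignment-stage filter),
then ≥ 10 non-duplicate unique reads **and** ≥ 10% of the overlapping
canonical junction. "Overlapping canonical junction" is not defined precisely
in the source methodology; here it is the set of annotated junctions sharing
a donor or acceptor with the candidate, and the reference count is their
**maximum** in the same sample — the hardest denominator to pass. A `sum`
mode is available. A candidate with no annotated junction sharing either site
cannot be held to the fraction rule and passes it carrying a
`no_canonical_reference` flag. Every emitted event carries
`needs_manual_review`, the machine-readable stand-in for read-level (IGV)
confirmation.

Classification: both sites annotated + at least one whole exon bin inside the
intron → `exon_skip`; both sites annotated otherwise → `novel_pair`; one
annotated site → `novel_donor` / `novel_acceptor` (strand-aware).

**Intron retention** has no single-read signature at the junction level, so it
is codified as a conjunction: cohort usage ratio of the annotated junction
< 0.8 **and** mean intron coverage ≥ max(5×, 10% of flanking-exon coverage).
The usage ratio divides the sample's library-size-normalized junction count by
the median of the other samples'; library size is the sample's total unique
junction reads — robust for a targeted panel where gene-level totals are
dominated by pull-down efficiency. All four constants are configuration.

## PSI and exon usage

PSI uses junction-spanning reads only (never exon-body coverage): inclusion is
the **mean** of the two flanking inclusion junction counts (the single
available flank for terminal bins; a `sum` variant is provided since the
upstream protocol's exact variant is ambiguous), exclusion is the sum over
junctions bridging the bin entirely. Zero spliced reads leave PSI undefined
rather than zero.

Exon usage length-normalizes each bin's count (reads per kilobase) and divides
by the gene total, a per-gene transcripts-per-million scheme; fractions sum to
one per expressed gene and are invariant to global count scaling. A sample is
an outlier for a bin when its robust z-score (cohort median, MAD with the
1.4826 consistency factor) reaches 3.0 **and** its usage odds `f/(1-f)` differ
from the cohort-median odds by ≥ 1.6-fold. The odds ratio is used because
scaling one bin's count by k scales its usage odds by exactly k, so the
statistic reads as the fold-change of the underlying count and does not
saturate for high-usage bins. The fold guard exists because a visually-tuned
procedure implicitly requires the shift to be large, not merely many MADs of a
tight cohort; 1.6 holds the empirical false-positive rate on event-free
synthetic cohorts near 0.1 per 13-sample cohort while a 2-fold count shift is
detected with ~2σ margin against the ~11% count noise.

Gene-level expression is summarized as a robust z of log2 CPM-normalized gene
totals; |z| < 2 is read as "normal overall expression" and is attached to NMD
calls as context, replacing a full differential-expression fit, which a
13-sample heterogeneous cohort cannot support.

## Allele imbalance and NMD

Tests are exact binomial tails, never normal approximations. The depletion
test uses a null ALT proportion of **0.45**, a fixed allowance for
reference-mapping bias (estimating bias from data is out of scope; the
constant is configurable). The overexpression test assumes no bias (null 0.5).
With printed counts (181 REF, 110 ALT) the left tail is 0.0077; with
(286 REF, 360 ALT) the right tail at 0.5 is 0.00202 and the left tail at 0.45
is 1.0 (2 significant figures).

Classification of heterozygous truncating variants (nonsense, frameshift, or
splice-driven premature termination): `p_left < α` → `consistent_with_nmd`;
otherwise `escapes_nmd`, upgraded to `escapes_with_alt_overexpression` when
`p_right < α` (α = 0.05). A premature stop in the last coding exon is recorded
as supporting rationale for escape but never overrides the statistical call.
Sites without a testable imbalance result are `inconclusive`; non-truncating
or non-heterozygous variants are `not_applicable`.

At 300× site depth the depletion test detects a 50%-decayed allele
(ALT fraction ≈ 0.29) with power ≈ 1 and holds its size under the bias-only
null (rejection ≈ 0.04–0.05).

## Variant prioritization and linkage

The rarity cutoff (0.02) and the TraP probably-damaging boundary (0.93) are
documented inferred defaults: the motivating analysis retains variants up to
MAF 0.0151 and describes TraP scores "well above" the damaging threshold
without printing either constant. Frequency comparisons use the worst of
global and subpopulation AF. Variant–event linkage (±10 bp of an event's
splice sites; for exon skips also the skipped exon's boundaries, where leaky
exonic splice variants sit) promotes a variant to splice candidate regardless
of frequency. Prioritization is deterministic and order-independent; every
excluded variant carries a machine-readable reason.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
reads: baseline junction and exon-bin counts are negative-binomial around
`mean_junction_depth × gene_factor × junction_factor × library_factor`, with

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 13 | cohort size |
| `n_genes` | 20 | panel genes (real immune-gene symbols) |
| `mean_junction_depth` | 500 | expected unique reads per annotated junction |
| `depth_dispersion` | 0.01 | NB dispersion α (variance μ + αμ²) |
| `gene_factor_sigma` | 0.6 | log-normal spread of pull-down efficiency |
| `library_sigma` | 0.10 | log-normal spread of per-sample library size |
| `mapping_bias` | 0.45 | expected ALT fraction at balanced het sites |
| `variant_depth_factor` | 1.2 | site depth relative to junction depth |

The dispersion default merits a note: α = 0.01 gives a between-sample
junction-count CV of ≈ 11% after library normalization. A markedly noisier
cohort (α = 0.1, CV ≈ 33%) would make single-junction usage ratios
uninterpretable at any depth — and reading a 60%-of-expected usage off one
junction, as the diagnostic logic does, presupposes a technically tight
panel. The value is configurable for sensitivity analyses.

Events are injected by **exact reallocation** so the manifest magnitude is the
simulated effect size: a leaky skip moves a Binomial(depth, f) share of the
flanking inclusion reads onto the skip junction (conserving the locus total
read-for-read); a retention writes `round(u × expected depth)` into the
canonical junction and deposits complementary coverage in the intron; an
extended splice site moves a fixed fraction onto the shifted-acceptor
junction; truncations draw allele depths with the ALT share scaled by the
decay (or amplification) factor through
`p_alt = bias·d / (bias·d + 1 − bias)`. Genes hosting events have their gene
factor pinned to 1.0. Baseline cohorts also carry common heterozygous
polymorphisms (AF 0.30) that exercise the ASE machinery without producing
findings. All randomness flows from one seed through deterministic
substreams; outputs are byte-identical across runs.

What passing on synthetic cohorts does **not** show: robustness to alignment
artifacts, duplicate-marking errors, 3′ coverage decay, multi-transcript
genes (the simulator emits one transcript per gene; multi-transcript
flattening is exercised by unit fixtures), pseudogene cross-mapping, or
cohort batch structure. The generator validates the statistical logic and the
plumbing, not the upstream read processing.

## Degenerate inputs and tie-breaks

Undefined quantities stay undefined rather than defaulting to 0 or 1: PSI
without spliced reads, usage fractions of an unexpressed gene, usage ratios
with a zero cohort median, NMD calls without a testable site. Zero-MAD bins
flag only when the deviation itself is nonzero (infinite z) and the magnitude
guard passes. Events tie onto at most one gene via the shared-splice-site /
lexicographic rule. Retention tested without an intron-coverage table yields
`coverage_unavailable`, never a silent negative.

## Known limitations

- The retention rule requires an intron-coverage summary; without it retention
  is undetectable by design (flagged, not guessed).
- The 0.45 mapping-bias null is a fixed convention; strongly biased capture
  designs would need it re-estimated.
- The usage-outlier rule targets single-bin shifts; coordinated whole-gene
  isoform switches dilute into many small per-bin changes and are better
  caught by the usage-ratio and PSI machinery.
- Cohort-based normalization assumes no shared aberration: an event present in
  most samples would be normalized away.
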
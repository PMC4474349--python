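# Methods

## Problem setting

Bread wheat is an allohexaploid: each gene locus is usually present as three
homeologous copies, one per subgenome (A, B, D), diverged by point
substitutions.  Short RNA-seq reads therefore map to all three copies, and
per-copy expression can only be measured through the substitution sites that
distinguish the copies.  The package implements that measurement and the
downstream classification of expression bias and stress-response
partitioning, together with a generator of synthetic data whose ground truth
exercises every decision rule.

## Triplet construction

Cross-subgenome gene pairs are aligned globally (Needleman–Wunsch scoring
2/−1 with −5/−0.5 gaps via `Bio.Align.PairwiseAligner`; a non-overlapping
8-mer Jaccard screen skips hopeless pairs) or read from 12-column tabular
alignment files produced by an external search tool.  Identity is matched
columns over all alignment columns; coverage is the aligned (both-base)
length over the **shorter** sequence — the conservative reading, since the
published filters name only "75 % coverage" and "90 % similarity" with an
e-value cutoff of 1e-10.  Pass-filter pairs form a graph whose connected
components are kept iff they contain exactly one A, one B and one D gene
(components with duplicated or missing subgenomes are logged and dropped,
with no rescue of embedded sub-triplets) and, when chromosome-group
annotation is available for all three members, the groups agree.  "Similar
chromosomal position" has no published quantitative form; group equality is
our operationalization and is skipped when annotation is absent.

The triplet alignment is taken column-wise when the three sequences have
equal length (the no-indel synthetic regime) and otherwise by progressive
merging of the B and D pairwise alignments on A's coordinates.  Every
gap-free, N-free column with at least two distinct alleles is a diagnostic
site; its discrimination pattern is the partition of {A, B, D} induced by
the alleles (one-vs-two, or all distinct).

## Read classification and allocation

Only read pairs placed on all three copies of one triplet are classified.
Both mates are pooled: a copy supports the pair iff the observed base equals
that copy's allele at **every** diagnostic site either mate overlaps.  The
ten groups are the seven support patterns {A}, {B}, {D}, {A,B}, {A,D},
{B,D}, {A,B,D}; the {A,B,D} subclass that overlapped no site at all; and two
conflict classes (no copy consistent within one mate; mates individually
consistent but jointly contradictory).  The published description names ten
groups without enumerating them; this partition reproduces the described
behaviour (specific / two-way / three-way / discarded) and is isolated
behind one function.

Allocation is per triplet × sample: copy A receives
`n_A + n_AB·n_A/(n_A+n_B) + n_AD·n_A/(n_A+n_D) + n_ABD·n_A/(n_A+n_B+n_D)`
(symmetrically for B and D).  When an ambiguity class has a zero
specific-count denominator its mass is split equally among its members, so
classified non-conflict mass is conserved exactly (tested to 1e-9).
Conflict reads contribute nothing.

## Expression bias (ECT/UCT)

The two-count comparison is reduced to the exact binomial test of `x`
against `x + y` at success probability ½ — the canonical one-margin-fixed
exact test.  The two-sided p-value is the minimum-likelihood sum, which for
the symmetric null equals the doubled smaller tail; it is evaluated in exact
integer arithmetic (cumulative binomial coefficients, one float rounding at
the end), so tests agree with brute-force enumeration to 1e-12.  An
alternative reading — Fisher's exact test on the 2×2 table `[[x, y], [m, m]]`
with a fabricated equal-split expected row — is available behind
`method="fisher2x2"`; it is conservative relative to the binomial reduction
(the fabricated row absorbs half the deviation, deflating the effective
z-statistic by √2) and is off by default.  Fractional allocated counts are
rounded half-to-even before testing; no multiple-testing correction is
applied inside the balance gate (the published procedure states raw
p < 0.01).

A triplet is UCT iff in **each** control replicate at least one of the three
pairwise tests has p < 0.01, and Exp_max/Exp_min ≥ 1.5 on the mean of
library-size-normalized replicates — per-replicate significance with a
pooled ratio is the only reading consistent with both published gate
descriptions.  Zero-count triplets are UNTESTED.

Because three valid p < 0.01 tests have a union probability of at most 3 %
per replicate, the both-replicate false-significance rate of balanced
triplets is bounded by 0.09 %; the exact binomial gate measures ~0.01–0.09 %
at Poisson depth 200.  Power at the planted conditions is high: a 2-fold
dominant copy at depth 300 is recovered as UCT in >99 % of triplets.

## Stress-response partitioning

Per copy and stress condition, replicates are pooled and tested against the
pooled control with the same exact machinery at success probability
`Σlib_treat/(Σlib_treat+Σlib_ctrl)` (general success probabilities use a
log-pmf evaluation with a 1e-9 relative tie tolerance).  The fold change is
`((t+0.5)/L_t)/((c+0.5)/L_c)`; the 0.5 pseudocount keeps the downstream
ratio-of-fold-changes finite and is configurable.  The test is pluggable so
an overdispersion-aware alternative can be substituted; the operative
content — gating at |FC| ≥ 2 and Benjamini–Hochberg FDR < 0.01, adjusted
separately per stress-vs-control contrast across all homeolog genes — is
unchanged under substitution.  BH adjustment is delegated to
`statsmodels.stats.multitest` and verified against the step-up formula.

A triplet is *partitioned* in a condition when any pairwise linear-scale
ratio of copy fold changes is ≥ 2 or ≤ ½, and partitioned under stress when
flagged in ≥ 1 of the six stress conditions.  Stratum membership for the
ECT/UCT partitioning percentages uses this fold-change-ratio criterion
alone; the per-copy DE gate is computed and reported alongside.  The
12-category scheme is ours (the published category definitions are not
reproduced in the text): in the flagged condition with the largest maximum
pairwise ratio (ties by condition order), the category is the response
direction (sign of the largest |log2FC|) × the dominant subset — the copy
whose |log2FC| leads the runner-up by ≥ 1, else the leading pair if it leads
the last copy by ≥ 1, else the single leading copy (ties lexicographic).
2 directions × 6 subsets = 12 mutually exclusive classes, isolated behind
one function for replacement.

## Promoters and motif targets

Promoters are the 2 kb upstream of the first exon of genes with an annotated
start codon: plus strand `[start−2000, start−1]`, minus strand the reverse
complement of `[end+1, end+2000]` (1-based closed at the interface, 0-based
half-open internally), truncated with a warning at contig boundaries.
Scanning is forward-strand only with every overlapping occurrence reported;
the HSE reverse orientation is covered by the second listed pattern, and a
reverse-complement scan for the DRE is available behind a flag (off by
default, as the published orientations are explicit).  `N` in a promoter
matches nothing.  Patterns are IUPAC; the DRE alternative notation
normalizes to `DRCCGACNW`.

"Similar expression trend" is operationalized as a ternary signature:
log2FC ≥ 1 up, ≤ −1 down, else flat, per condition; DS/HD-induced means up
in ≥ 1 DS and ≥ 1 HD condition and not up in any HS condition (mirrored for
HS/HD).  A predicted target needs ≥ 1 hit of the group's motif **and** the
matching tag.  A Pearson-correlation criterion (r ≥ 0.8 across conditions)
is provided as an alternative.

## Synthetic data

One seed drives everything through `numpy.random.SeedSequence` with a fixed
spawn key per stage (0 triplets, 1 counts, 2 reads, 3 promoters), so outputs
are bit-reproducible and stages are independently re-runnable.  Defaults
mirror the emulated experiment: 1.5-kb genes; 2 % pairwise divergence
(per-copy substitution rate solved from `2m − (4/3)m² = d` so the *pairwise*
rate is exactly the nominal value); no indels, since the read-group logic is
defined over substitution SNPs; 100-bp paired-end reads on 200-bp fragments
with per-base error 0.001 and constant quality `I` (quality is unused);
7 conditions × 2 replicates; Poisson counts at depth 300 per copy with
per-sample library factors U(0.85, 1.15) (a fixed-dispersion gamma-Poisson
option stress-tests overdispersion); planted unequal contribution in 50 %
of triplets at ratio 2; planted partitioned responses in 30 % at fold
change 4 (⅓ down-regulated) over realistic condition families (DS, HS, HD,
DS+HD, HS+HD); a further 20 % respond coordinately (all copies, ratio 1).
Promoter backgrounds are i.i.d. uniform with non-overlapping planted motif
realizations at recorded offsets.

What the generator does **not** emulate — GC and positional bias,
multi-isoform genes, indel divergence, overdispersion beyond the NB option,
mapping errors — bounds what green tests prove: they validate the decision
rules and their calibration under the stated model, not performance on real
libraries.

## Problem sizes and numerics

Test and acceptance cohorts are sized for seconds-to-minutes runtimes while
keeping Monte-Carlo error well inside the asserted margins: exact-test
enumeration over all totals ≤ 200; 1,000 random 2-kb promoters for scanner
equivalence; 10,000 group-count vectors for conservation; 10,000 balanced
triplets for calibration; 2,000 planted UCTs for recovery; a 200-triplet
partitioning cohort; and a 60-triplet end-to-end pipeline at depth 150.
Degenerate inputs are contracts, not crashes: zero totals are untested/NA,
zero allocation denominators fall back to equal splits, empty alignments
score zero, and zero divergence warns that every read will be three-way
ambiguous.

## Known limitations

Real-data mode consumes SAM placements and tabular alignments but no
aligner is bundled; the balance test ignores biological overdispersion
between replicates (by design, matching the published gate) so its
false-UCT rate on real data depends on replicate quality; the 12-category
scheme and the 10-group composition are package definitions where the
publication left them unspecified; triplet building assumes exactly three
subgenomes.
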
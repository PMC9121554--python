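# Methods

This note documents the models behind each stage of the pipeline, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer should know
about.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and interval algebra

All intervals are 0-based half-open (BED convention); chromosome order is
lexicographic.  Overlap means ≥ 1 shared base (the bedtools default) unless
a caller passes `min_overlap`; strand is carried but ignored by overlap
operations, since ATAC peaks are unstranded — strand matters only for
promoter windows, regulatory domains and motif scanning.  `intersect`,
`merge`, `subtract` and `overlap_counts` are implemented directly (sorted
sweep + vectorized candidate pruning) and the test suite holds them to
exact agreement with naive all-pairs / base-resolution oracles on
1,000-interval random sets, which is the regime the package targets
(peak lists of 10²–10⁵ intervals).

## Peak annotation

Promoter = 2 kb upstream to 1 kb downstream of the TSS, mirrored on the
minus strand and clipped at the origin.  The TSS of a minus-strand gene is
its last covered base (`body.end − 1`).  Classification is peak-level (a
peak is counted once, not per base) with precedence promoter > exon >
intron > intergenic; the intron space is defined literally as gene bodies
minus exons minus promoter windows so the genic spaces stay consistent
under any precedence permutation.  A base-level variant was considered and
rejected as the default because category *proportions of peaks* are the
quantity of interest downstream.  Duplicate gene ids in a BED12 input are
collapsed to the longest body (logged), so one model per gene is
guaranteed.

## Differential accessibility

The differential stage replaces the usual black-box differential-binding
package call with a specified, oracle-checkable statistic:

* **Size factors** — median-of-ratios with a geometric-mean reference over
  peaks with all-nonzero counts; when no such peak exists, total-count
  scaling normalized to geometric mean 1 (logged).
* **Dispersion** — a single NB dispersion α (variance = μ + αμ²) pooled
  over all peaks and conditions by method of moments:
  α̂ = Σ(v − m) / Σ(m² − v/n_rep) on normalized counts.  The −v/n_rep term
  corrects the bias of m² as an estimator of μ² (E[m²] = μ² + var(m));
  without it α̂ is systematically low (≈ 8 % at μ = 100, n = 2) and the
  test anti-conservative.  One common dispersion (no trend/shrinkage) is a
  deliberate scope choice: with two replicates per condition, per-peak
  dispersions are too noisy to be useful, and the common-α LRT is the
  quantity the calibration tests certify.
* **Test** — per-peak likelihood-ratio test of equal base means between
  conditions, raw counts modelled as NB with per-sample size-factor
  offsets; the group-mean MLE solves the score equation by a vectorized
  fixed-point iteration (exact in one step for equal size factors or
  α = 0, which reduces to the Poisson LRT).  2(ℓ₁ − ℓ₀) is referred to
  χ²₁; BH adjustment across peaks.  A `dispersion` argument overrides α̂
  with a known value.
* **log2FC** — log2((mean_A + 0.5)/(mean_B + 0.5)) on normalized means;
  the 0.5 pseudocount avoids infinities at empty peaks.

Unique-peak calling defaults to **occupancy** mode (consensus across all
replicates of one condition, zero ≥ 1 bp overlap with every replicate of
the other) because presence/absence across replicate peak sets is how
condition-specific peaks are reasoned about in replicate-overlap (Venn)
analyses; **affinity** mode (q < FDR and |log2FC| > threshold, default 1)
serves count-aware analyses.  FDR 0.05 is an exposed default, not a claim
about any particular study.

## Expression integration

Gene "coordinates" are the full transcript span.  A condition's concordant
genes are those with padj < α (default 0.05), log2FC in the condition's
direction (condition A pairs with "up" since log2FC is A vs B), and ≥ 1
linked condition-specific peak.  Genes linked by peaks but absent from the
expression table are excluded and logged.

## Enhancers, regulatory domains and super-enhancers

Enhancers are H3K27ac intervals minus promoter windows.  Region→gene
association uses the basal-plus-extension convention of GREAT with that
tool's documented defaults (basal 5 kb upstream / 1 kb downstream of the
TSS, strand-aware; extension up to 1 Mb each way, truncated at the nearest
neighboring basal domain; a gene's basal domain is always kept even when
neighbors overlap).  All three distances are configurable.  Super-enhancer
calling is out of scope (SEs are an input catalog); the package reports SEs
containing ≥ 1 condition-unique peak, their associated genes (by the same
domain rule, or by a caller-supplied SE→gene table such as a catalog's own
assignment), and an upregulated flag per gene.  Gene-based hypergeometric
enrichment is used for term analysis of associated genes rather than a
genomic-fraction binomial test — a simpler statistic with an exact
independent oracle (Fisher), at the cost of ignoring region length bias.

## Motif scanning and enrichment

A PWM is stored as per-position base probabilities with a pseudocount
(default 1e−3) renormalized on load; scoring is log2 odds against the
background (uniform by default).  JASPAR and MEME-minimal files are parsed
via Bio.motifs.

**Score p-values.**  P(S ≥ s) for a background-drawn k-mer is computed by
dynamic programming that expands the score distribution column by column.
For widths ≤ 10 every achievable float score is kept (4^w ≤ ~10⁶ states),
so the tail is exact to float addition; for wider matrices the same
recursion runs on a discretized lattice with 1e−3-bit bins, making per-hit
p-values approximate to about w·0.5e−3 bits of score, which is negligible
at scanning thresholds.  The distribution is cached per PWM, and scanning
converts the p-value threshold to a score threshold once.

**Scanning** scores both strands at every offset (minus strand via the
reverse-complemented matrix at the same forward offset); windows containing
non-ACGT symbols are skipped and logged; hits with p < threshold (default
1e−4, the conventional scanner default) are reported sorted by (peak,
offset, strand).  Note the floor of achievable p-values is 4^−w: a 6-bp
E-box (CAGCTG) can never reach 1e−4 (best p = 2.4e−4), so demonstrations
with that matrix use an explicit looser threshold; the shipped fixture
library (synthetic E-box/ASCL1-like, E-box/NEUROD1-like and AP-1-like
matrices, clearly labelled as hand-built fixtures) uses width 11 so the
default threshold admits essentially only near-consensus matches.

**Background and fold.**  The background is a mononucleotide scramble
(uniform permutation; composition exactly preserved, deterministic given a
seed); a dinucleotide-preserving Euler-path shuffle is available behind a
flag but is not the default, since composition-preserving scrambling is the
conventional null here.  Fold = (observed + c)/(background_mean + c) with
c = 1 by default, threshold 2, n_shuffles = 10.  The pseudocount is the
package's regularization choice: on small peak sets expected background
counts are O(1), and a raw ratio lets a single chance occurrence clear any
threshold; c = 1 requires observed ≥ 2·background + 1, which makes the
enriched flag stable without touching the threshold.  `pseudocount=0`
restores the raw ratio with an ε = 0.5/n_shuffles denominator floor, and
observed = 0 always reports fold 0.  Fold calibration on null sequence is
only meaningful when the expected count is well above zero (otherwise the
fold is 0 or ∞-like by construction), so the null-calibration experiments
scan at p < 0.01 on ~2 kb of sequence (expected ≈ 30 hits); this is a
property of count ratios, not of this implementation.  Overlapping hits
are all counted — occurrence counts are raw, with no greedy masking.

## Network

The bipartite TF→gene graph connects each *enriched* motif's TF (heterodimer
ids such as FOSL1::JUN stay single nodes) to the selected concordant genes
having ≥ 1 linked condition-specific peak with ≥ 1 hit; multiple peaks per
(TF, gene) collapse into one edge that retains all peak-level evidence.
Hubs are reported as an out-degree ranking — a descriptive output, no test
is attached.  Pairwise TF target overlap is |∩| and Jaccard.  GraphML
serializes evidence as a `peak:offset:strand` semicolon string (GraphML
attributes cannot hold lists); round-tripping restores the edge set and
evidence exactly.

## Term enrichment

Upper-tail hypergeometric P(X ≥ k) per term, BH per category (BP/CC/MF/
KEGG/other), matching the per-category panels such analyses report; pooled
correction is available.  The universe defaults to the supplied gene table
and is a consequential, user-visible choice.  An EASE-style offset (test
k − 1) is exposed for compatibility with DAVID-like scores but is off by
default — the plain hypergeometric has an exact independent oracle
(one-sided Fisher), which the tests exploit.

## Synthetic data generator

The generator emulates the statistical structure of a two-condition,
two-replicate accessibility study with a one-sided program: condition A
(the "tumor" state) gains accessibility at genes that are upregulated in A
versus B.  Defaults: 2 chromosomes × 900 kb of i.i.d. uniform sequence;
150 genes (2–5 kb, ≥ 6 kb apart, 2–4 exons, random strand); 150 shared +
50-per-condition unique peaks of 200–400 bp; NB counts with mean 100
(dispersion 0.1) where a sample's condition has the peak open and mean 5
otherwise; implant rate 0.5; coupling 0.6; upregulated log2FC from a
positively truncated Normal(2, 0.5) with padj ~ U(0, 0.05), all other
genes Normal(0, 0.5) with padj ~ U(0.05, 1); H3K27ac coverage 0.8 of
condition-A peaks (± 500 bp pads) with 10 designed super-enhancer
clusters.  These sizes keep a full pipeline run under ~5 s while leaving
every recovery statistic well away from small-sample degeneracy.

Structural choices worth knowing:

* **Uniform base composition** keeps the scramble background unbiased, so
  enrichment folds have expectation ≈ 1 on un-implanted sequence by
  construction.
* **Single seed, named stages.**  All randomness flows from one integer
  seed through named `SeedSequence` children (genome, genes, peaks, jitter,
  counts, implant, expression, h3k27ac), so identical seeds give
  byte-identical files and stages are independently reproducible.
* **True peaks never overlap**; per-sample peak boundaries are jittered by
  ≤ 20 bp to mimic replicate-to-replicate peak-call wobble without breaking
  presence/absence structure, and implants stay ≥ 20 bp inside the peak so
  every replicate's call contains the site.
* **Condition-A-unique peaks are ≥ 3.6 kb apart and coupled genes pairwise
  non-adjacent.**  This guarantees that H3K27ac pads never chain into
  accidental ≥ 3-interval super-enhancer clusters and that each designed SE
  is attributable to exactly one upregulated gene (adjacent regulatory
  domains abut, so a flagged neighbor would make the attribution
  ambiguous).  Non-coupled peaks avoid flagged gene bodies so the coupling
  truth stays exact.
* **Super-enhancers are derived, not asserted**: the full H3K27ac set is
  merged with a 1 kb gap and components with ≥ 3 constituent intervals are
  emitted as SEs, so the generator's own SE definition is exercised by the
  same interval code the pipeline uses.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level artifacts (no FASTQ/BAM; counts are
drawn per peak, so fragment-length and Tn5-bias effects are absent),
sequence composition structure (CpG islands, repeats — motif backgrounds on
real genomes are harder than on uniform sequence), dispersion trends with
coverage, any coupling in condition B (its concordant-gene set is empty by
construction), and indirect TF regulation (truth edges exist only where a
motif instance was physically implanted).

## Numerical details and degenerate inputs

* Hypergeometric tails via `scipy.stats.hypergeom.sf`, BH via statsmodels
  `multipletests`; both sit behind the package's own validated surfaces.
* The NB likelihood switches to Poisson below α = 1e−8; LRT statistics are
  clipped at 0 before χ² referral.
* `score_pvalue` returns 1 at or below the minimum achievable score and 0
  above the maximum; a 1e−9 tolerance absorbs float summation-order
  differences between scan scores and the cached distribution.
* Empty inputs: empty peak sets annotate to an error (`no peaks to
  annotate`); an empty query gives an empty enrichment table; an empty
  network logs a warning rather than raising; `merge`/`subtract` accept
  empty operands.
* Placement density is validated up front: gene slots and peak footprints
  that cannot fit raise `PlacementError` naming the violated capacity
  rather than looping forever.

## Known limitations

Occupancy-based unique peaks inherit the instability of peak calling near
detection thresholds (mitigated here only by consensus-across-replicates);
the common-dispersion LRT is slightly liberal in the far tail with two
replicates (its 5 % null rate is certified within the binomial 99 % CI at
2,000 peaks, not beyond); regulatory-domain association ignores chromatin
contacts (as does the convention it follows); and motif fold enrichment has
no significance calibration beyond the fold threshold — it is a descriptive
screen, which is why the network stage gates on it rather than ranking by
it.
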
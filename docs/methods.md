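# Methods

## The analysis model

`enhancerlink` operationalizes a common two-cell-type enhancer study design.
Enhancers are intervals marked by H3K4me1; *cell-type specificity* is
differential tag density between the two cells; *activity* is the presence
of H3K27Ac; *openness* is FAIRE-peak intersection; and enhancer-gene
coupling is inferred statistically from the spatial co-occurrence of
specific enhancers and cell-type-matched overexpression, never from physical
contact data. All coordinates are BED-style 0-based half-open; every
distance in the pipeline is |TSS − locus midpoint| with strict inequality at
window edges, the midpoint being floor((start+end)/2).

### Differential calling

Each candidate locus is quantified as the tag count in
[midpoint − flank, midpoint + flank), flank 500 bp, normalized to tags per
10⁷ sequenced tags. The differential test is a two-sided Poisson test of
`tags_a` against `tags_b · L_a/L_b` (library-size ratio), p = 2·min(lower,
upper tail) capped at 1, with Benjamini–Hochberg adjustment across loci and
a 0.10% FDR gate. This is a re-specification of what upstream peak callers
do internally; their exact statistic is not published, so genome-scale peak
counts from real data are not comparable quantities. The log₂ fold-change
adds a one-tag pseudocount to the raw counts *before* normalization,
log₂(((t_a+1)/L_a)/((t_b+1)/L_b)): this keeps the statistic exactly
invariant under joint rescaling of both library sizes, which a pseudocount
on the normalized scale would not. Specific sets take the top-N by
fold-change (ties: larger normalized count in the favoured cell, then
coordinate order — selection is fully deterministic); the two directions
are disjoint by construction. The shared set ranks by ascending |log₂ FC|
among loci whose density exceeds background in *both* cells; background
defaults to 2× the expected uniform count per window estimated from each
track's depth and extent, because any fixed floor fails across sequencing
depths.

### Poised/active classification

The feature is the normalized H3K27Ac count in ±1 kb of the midpoint. The
two-cluster split is the *exact* optimal one-dimensional 2-means: features
are sorted and every split point scored by within-cluster sum of squares
with prefix sums (O(n log n)). Lloyd iteration from fixed percentile
initialization was considered and rejected: it approximates the same
optimum but is not guaranteed to reach it, whereas the split search is
globally optimal, deterministic and trivially testable against an O(n²)
oracle. A `method="vector"` option clusters the binned ±1 kb density
profile with standard seeded k-means instead, for users who prefer
profile-shape clustering; the scalar default is recommended for
reproducibility. The cluster with the higher mean is *active*. All-equal
features raise a degenerate-clustering error rather than returning an
arbitrary split.

### Expression association and the null

Genes partition into over_A / over_B / unchanged by adjusted p < 0.05
(strict) and the sign of the log fold-change. The expression universe for
control sampling is the union of both differential sets and genes expressed
in both cells. Window scans count each gene once per window regardless of
how many loci fall inside; counts are therefore monotone in window size,
and ring (interval) scans partition the ≤ max-window genes.

The "direct simulation" null resamples gene sets of size n (default 300)
from the universe and counts members with an enhancer within the window.
Because a simple random sample's flagged count is exactly hypergeometric,
each replicate draws a hypergeometric variate directly — distributionally
identical to materializing the gene sets and orders of magnitude faster;
the equivalence is asserted in the tests against both an explicit
gene-resampling loop and the closed-form hypergeometric quantiles. The 95%
CI is the empirical 2.5th/97.5th percentile with linear interpolation,
rounded outward to integers (floor/ceil) so the reported interval never
understates the simulated spread.

### Motif scanning and enrichment

PFMs (JASPAR via Biopython, or minimal MEME text) become log₂-odds PWMs
with a background-weighted pseudocount (default 0.1):
score(b,i) = log₂((c(b,i) + pc·bg_b)/(Σc(·,i) + pc)/bg_b). The score
threshold for a target p-value (default 10⁻⁴) comes from the exact
distribution of window scores under a 0-order background: per-column score
distributions are discretized to an ε = 0.01-bit grid and convolved
position by position; the threshold is the smallest achievable grid score
whose upper tail is ≤ p, relaxed by the maximal rounding error (width·ε/2)
so continuous window scores are judged consistently with the grid. The
total threshold error is therefore bounded by width·ε (≈0.1–0.2 bits for
typical widths); the DP is verified against exhaustive k-mer enumeration
for widths ≤ 6 and against Biopython's independent score-distribution
implementation. Both strands are scanned; windows containing N are skipped;
a region counts once if any window reaches the threshold. Short motifs may
not reach 10⁻⁴ at all (a width-6 motif's best tail is 4⁻⁶ ≈ 2.4·10⁻⁴);
the maximum score is then used with a warning.

Enrichment between two region sets is the per-motif 2×2 Pearson chi-square
(no continuity correction) on regions-with-hit counts, filtered at raw
p < 0.05 and sorted ascending. No multiplicity correction is applied to the
filter — this mirrors the per-test convention of the analysis the package
reproduces — but a BH-adjusted column is emitted alongside for users who
want it. Motifs hit in no region (or every region) of both sets are
untestable and skipped.

### Target assignment and term enrichment

Genes within 100 kb of both cell types' specific sets are ambiguous and
excluded. Active enhancers are then matched many-to-many to exclusive,
concordantly overexpressed genes within 100 kb; multiplicity is summarized
as exact degree histograms in both directions. Term enrichment between two
gene sets is the same 2×2 chi-square per term (members vs non-members),
reported as −log₂ p; the significance threshold is a flag (default 0.05,
since published analyses of this kind vary between 0.02 and 0.03).

### Feature annotation

Locus features resolve by midpoint with fixed priority promoter > exon >
intron > intergenic, giving exactly one label per locus. The promoter is a
strand-aware (−1000, +100) bp window around the TSS — the conventional
annotator default; the window is a parameter because no single value is
canonical.

## The synthetic-data generator

The generator emulates the *structure* of the real study at configurable
scale. Defaults mirror the study conditions: 2,000 specific loci per cell
type, 2,000 shared, 6,902 genes, half the loci active (p_active = 0.5),
half nucleosome-depleted (p_faire = 0.5), matched-cell H3K4me1 enrichment
60× background, shared/H3K27Ac/FAIRE enrichments 20×/30×/20×, triangular
tag peaks of half-width 150 bp (echoing the triangle model of upstream
peak callers), and motif planting rates (0.4, 0.05) between the two region
sets. Expression coupling is
P(matched overexpression) = 0.5·exp(−d/250 kb) + 0.2 with a symmetric 0.2
baseline per direction — strong at 100 kb, gone by ~750 kb; a step-shaped
coupling (flat excess within a range) is available for calibration
experiments. Each chromosome has a gene-rich 60% and a gene desert, so a
configured fraction of enhancers (default 0.7) can be placed within 100 kb
of a TSS and the rest genuinely TSS-distal; all locus midpoints are ≥ 1 kb
apart or a capacity error is raised. Everything is deterministic per seed
(independent numbered substreams per generator stage), and planted labels
live only in `truth_*` tables that are never written into pipeline inputs.

What the generator does *not* emulate — and what passing tests therefore do
not demonstrate about real data: read-level noise and mappability,
replicate structure, peak-width variation, probe-level expression
measurements, correlated enhancer clusters, chromatin-domain structure, and
any trans (inter-chromosomal) regulation. Recoveries near 100% on synthetic
worlds reflect the planted effect sizes (60× enrichment is deliberately
unambiguous), not expected real-data performance.

## Problem sizes and numerical choices

Tests and the acceptance script run scaled-down worlds chosen to keep the
full suite fast while preserving every structural feature: typically 2–3
chromosomes of 10–25 Mb, 1,500–2,000 genes, 80–300 loci per set, tag depth
3–5·10⁵ (≈10–20 background tags per 1 kb window, so the 60× planted ratio
is detectable but finite). Sparse worlds (80 loci per type in 50 Mb) are
used wherever distance resolution matters, because dense placement
saturates every window ≥ 100 kb and flattens the ratio profile — an
instructive artefact, not an error. Calibration experiments use
k = 10,000–100,000 null replicates; 100 replicate worlds for parameter
recovery; 200 for the symmetric-rate null, with binomial acceptance bands
at the 99.8% level around the nominal 5% rejection rate.

Tie-breaks are everywhere lexicographic (coordinate order, then gene id)
for bit-reproducibility. Quantiles use linear interpolation. Degenerate
inputs (zero marginals, identical features, empty windows, regions shorter
than the motif) raise or flag rather than silently returning defaults.

## Known limitations

* The Poisson differential test ignores biological replicate variance
  (inputs are single combined tracks, as in the emulated design).
* The 0-order background for motif scanning underestimates hit rates in
  CpG-skewed or repetitive sequence; higher-order backgrounds are out of
  scope.
* Target assignment is purely distance + concordance; it cannot distinguish
  direct from passenger associations and deliberately excludes genes near
  both cell types' enhancers.
* Published genome-wide counts from the emulated study (total peak numbers,
  poised/active splits, target-gene counts) depend on the original
  sequencing data and are not reproducible from synthetic worlds; only the
  printed-table arithmetic (the 2×2 chi-square, the enrichment ratios) and
  the method's calibration properties are.
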
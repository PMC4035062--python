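# enhancerlink

Identify cell-type-specific enhancers from two-condition histone-mark tag
data and relate them to nearby gene expression.

Given H3K4me1 tag tracks for two cell types (say a normal epithelial line A
and a cancer line B), candidate peak intervals, an H3K27Ac track, FAIRE
(nucleosome-depletion) peaks, a two-condition expression table and motif
matrices, `enhancerlink`:

1. quantifies each candidate locus in both cells (tags per 10⁷, ±500 bp of
   the midpoint), tests differential density with a library-ratio Poisson
   test under Benjamini–Hochberg control (FDR ≤ 0.001), and selects the
   top-*N* loci per direction by fold-change — the **cell-type-specific
   enhancer sets** — plus a *shared* set of similar-density loci used as a
   null comparison;
2. classifies each specific locus **poised** vs **active** by two-cluster
   k-means on its H3K27Ac density (±1 kb), and flags nucleosome depletion by
   FAIRE-peak intersection (±500 bp);
3. relates enhancer sets to expression: genes are `over_A` / `over_B` /
   `unchanged` (adjusted p < 0.05 and the sign of the log fold-change), and
   counted inside a ladder of TSS-to-midpoint windows (±20 kb … ±2 Mb). The
   excess of enhancer-adjacent genes among the top-300 differential genes is
   judged against a **direct-simulation null**: k = 100,000 random gene sets
   of the same size drawn from the expression universe, with an empirical
   95% CI on the adjacent-gene count (the count per draw is exactly
   hypergeometric);
4. scans region sequences with log-odds PWMs at an exact score-distribution
   p-value threshold (default 10⁻⁴, dynamic programme over discretized
   per-column score distributions) and tests per-motif enrichment between
   two region sets with the 2×2 Pearson chi-square (no continuity
   correction):

   χ² = N(ad − bc)² / ((a+b)(c+d)(a+c)(b+d)),  df = 1;

5. assigns **putative target genes** to active enhancers: genes within
   100 kb of both cell types' sets are excluded, the remainder matched
   many-to-many to concordantly overexpressed genes, with degree histograms
   and per-ontology-term chi-square comparisons (−log₂ p).

A seeded synthetic-data generator (`enhancerlink.simulate`) produces whole
worlds — genome, genes, planted enhancers with hidden cell-type/state/FAIRE
labels, tag tracks, coupled expression, motif-planted sequences, biased term
maps — so every stage is testable against known ground truth.

## Worked example

```python
from enhancerlink import (
    EnhancerExpressionAssociation, differential_loci, select_top_specific,
    classify_poised_active, generate_dataset,
)
from enhancerlink.simulate import SyntheticConfig

world = generate_dataset(SyntheticConfig(
    chrom_sizes={"chr1": 25_000_000, "chr2": 25_000_000},
    n_genes=2000, n_specific_enhancers_per_type=80,
    n_shared_enhancers=0, n_decoy_loci=0, seed=1), with_tags=False)

model = EnhancerExpressionAssociation(
    world.enhancer_intervals("a"), world.genes, world.expression, direction="a")
print(model.fit(k=100_000, seed=0).summary())
```

```
Enhancer-expression association
===============================================
direction                 a
loci                      80
genes                     2000
universe size             2000
flagged in universe       615
window (bp)               100000
top-300 observed count    164
random-control count      89
enrichment ratio          1.8
null 95% CI (k=100000)   [78, 107]
outside null CI           True
...
 window  n_genes  over_a  over_b  unchanged  ...  ratio_a_over_b
  20000      142      85      16         41  ...        5.312500
 100000      615     297     105        213  ...        2.828571
 750000     1813     546     525        742  ...        1.040000
```

164 of the top-300 genes overexpressed in cell A have an A-specific
enhancer within 100 kb — 1.8× the random-control count and far above the
null CI of [78, 107] — and the over_A/over_B ratio decays from 5.3 in the
±20 kb window to ~1 by ±750 kb: expression coupling is strongest close to
the enhancer and gone beyond the planted coupling scale.

The same stages are available from the shell:

```bash
enhancerlink simulate --seed 1 --outdir world/ --scale 0.2
enhancerlink call-specific --tags-a world/tags_h3k4me1_a.bed \
    --tags-b world/tags_h3k4me1_b.bed --loci world/candidate_loci.bed \
    --direction a --n 400 --out specific_a.tsv
enhancerlink classify-states --loci world/candidate_loci.bed \
    --k27-tags world/tags_h3k27ac_a.bed --faire-peaks world/faire_peaks_a.bed \
    --out states.tsv
```

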
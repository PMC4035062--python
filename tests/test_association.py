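"""Gene categorization, window scans, the resampling null and the model surface."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from enhancerlink.association import (
    DEFAULT_WINDOWS,
    EnhancerExpressionAssociation,
    categorize_genes,
    define_universe,
    direct_simulation_ci,
    enrichment_ratio,
    genes_within_window,
    interval_scan,
    min_distance_to_loci,
    sample_controls,
    scan_table,
    top_differential,
    window_scan,
)
from enhancerlink.intervals import GeneModel, GenomicInterval


def _expr(rows):
    return pd.DataFrame(rows, columns=["gene_id", "log_fc", "adj_p"])


class TestCategorizeGenes:
    @pytest.mark.parametrize(
        "log_fc,adj_p,expected",
        [
            (1.0, 0.04, "over_a"),
            (-1.0, 0.04, "over_b"),
            (1.0, 0.5, "unchanged"),
            (1.0, 0.05, "unchanged"),  # boundary: strict inequality
            (0.0, 0.01, "unchanged"),  # significant but no direction
        ],
    )
    def test_three_way_partition(self, log_fc, adj_p, expected):
        cats = categorize_genes(_expr([("g", log_fc, adj_p)]))
        assert cats["g"] == expected

    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            categorize_genes(_expr([("g", 1, 0.01), ("g", -1, 0.01)]))


class TestTopDifferential:
    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(23)
        df = _expr(
            [
                (f"g{i:04d}", float(rng.normal()), float(rng.uniform(0, 0.2)))
                for i in range(2000)
            ]
        )
        top = top_differential(df, n=100, direction="b")
        brute = df[(df.adj_p < 0.05) & (df.log_fc < 0)].copy()
        brute["key"] = -brute.log_fc.abs()
        brute = brute.sort_values(["key", "gene_id"]).gene_id.head(100).tolist()
        assert top == brute

    def test_shortfall_warns_and_returns_all(self):
        df = _expr([("g1", 2.0, 0.01), ("g2", 1.0, 0.01)])
        with pytest.warns(UserWarning, match="only 2"):
            top = top_differential(df, n=300, direction="a")
        assert top == ["g1", "g2"]


class TestDefineUniverse:
    def test_published_universe_arithmetic(self):
        rows = (
            [(f"a{i}", 1.0, 0.01, True) for i in range(3174)]
            + [(f"b{i}", -1.0, 0.01, True) for i in range(2670)]
            + [(f"u{i}", 0.0, 0.5, True) for i in range(1058)]
        )
        df = pd.DataFrame(rows, columns=["gene_id", "log_fc", "adj_p", "expressed_both"])
        assert len(define_universe(df)) == 6902

    def test_non_expressed_unchanged_genes_excluded(self):
        df = pd.DataFrame(
            [("a", 1.0, 0.01, False), ("u1", 0.0, 0.5, True), ("u2", 0.0, 0.5, False)],
            columns=["gene_id", "log_fc", "adj_p", "expressed_both"],
        )
        assert define_universe(df) == ["a", "u1"]


def _gene(gene_id, chrom, tss, strand="+"):
    if strand == "+":
        return GeneModel(gene_id, chrom, tss, tss + 1000, strand)
    return GeneModel(gene_id, chrom, tss - 999, tss + 1, strand)


class TestGenesWithinWindow:
    def test_window_edge_is_exclusive(self):
        loci = [GenomicInterval("chr1", 99_500, 100_500)]  # midpoint 100,000
        genes = [_gene("at_edge", "chr1", 150_000), _gene("inside", "chr1", 149_999)]
        hit = genes_within_window(loci, genes, window=50_000)
        assert hit.gene_id.tolist() == ["inside"]

    def test_gene_flanked_by_loci_reported_once_with_min_distance(self):
        loci = [
            GenomicInterval("chr1", 0, 1000),  # midpoint 500
            GenomicInterval("chr1", 10_000, 11_000),  # midpoint 10,500
            GenomicInterval("chr1", 30_000, 31_000),
        ]
        genes = [_gene("g", "chr1", 11_000)]
        hit = genes_within_window(loci, genes, window=100_000)
        assert len(hit) == 1
        assert hit.min_distance.iloc[0] == 500

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(31)
        loci = [
            GenomicInterval(f"chr{rng.integers(1, 3)}", int(s), int(s) + 1000)
            for s in rng.integers(0, 10**6, size=300)
        ]
        genes = [
            _gene(f"g{i}", f"chr{rng.integers(1, 3)}", int(rng.integers(0, 10**6)))
            for i in range(300)
        ]
        got = genes_within_window(loci, genes, window=50_000)
        got_map = dict(zip(got.gene_id, got.min_distance))
        for g in genes:
            dists = [
                abs(g.tss - iv.midpoint) for iv in loci if iv.chrom == g.chrom
            ]
            expected = min(dists) if dists else math.inf
            if expected < 50_000:
                assert got_map[g.gene_id] == expected
            else:
                assert g.gene_id not in got_map


@pytest.fixture(scope="module")
def sparse_assoc(sparse_world):
    loci = sparse_world.enhancer_intervals("a")
    return sparse_world, loci


class TestWindowScan:
    def test_counts_monotone_in_window_size(self, sparse_assoc):
        world, loci = sparse_assoc
        results = window_scan(loci, world.genes, world.expression)
        totals = [r.n_genes for r in results]
        assert totals == sorted(totals)

    def test_empty_window_is_flagged(self):
        loci = [GenomicInterval("chr9", 0, 1000)]
        genes = [_gene("g", "chr1", 500_000)]
        (res,) = window_scan(loci, genes, _expr([("g", 1.0, 0.01)]), windows=[1000])
        assert res.empty and res.n_genes == 0

    def test_unsorted_windows_rejected(self, sparse_assoc):
        world, loci = sparse_assoc
        with pytest.raises(ValueError):
            window_scan(loci, world.genes, world.expression, windows=[100, 50])

    def test_ratio_decays_with_distance_under_planted_coupling(self, sparse_assoc):
        world, loci = sparse_assoc
        t = scan_table(window_scan(loci, world.genes, world.expression))
        ratios = t["ratio_a_over_b"].tolist()
        # enrichment strongest in the tightest window, decayed beyond ~750 kb
        assert ratios[0] > 2.0
        assert ratios[5] < 1.3
        assert all(x > y for x, y in zip(ratios[:6], ratios[1:7]))

    def test_shared_loci_show_balanced_expression(self, small_world):
        shared = small_world.enhancer_intervals("shared")
        results = window_scan(shared, small_world.genes, small_world.expression)
        r100k = [r for r in results if r.window == 100_000][0]
        assert 0.8 < r100k.ratio_a_over_b < 1.25


class TestIntervalScan:
    def test_single_ring_reproduces_full_window(self, sparse_assoc):
        world, loci = sparse_assoc
        ring = interval_scan(loci, world.genes, world.expression, boundaries=[2_000_000])
        (win,) = window_scan(loci, world.genes, world.expression, windows=[2_000_000])
        assert ring.n_genes.iloc[0] == win.n_genes
        assert ring.over_a.iloc[0] == win.count_over_a

    def test_rings_partition_the_in_range_genes(self, sparse_assoc):
        world, loci = sparse_assoc
        rings = interval_scan(loci, world.genes, world.expression)
        (win,) = window_scan(
            loci, world.genes, world.expression, windows=[DEFAULT_WINDOWS[-1]]
        )
        assert rings.n_genes.sum() == win.n_genes

    def test_matches_brute_force_ring_assignment(self, sparse_assoc):
        world, loci = sparse_assoc
        boundaries = [50_000, 200_000]
        rings = interval_scan(loci, world.genes, world.expression, boundaries=boundaries)
        dist = min_distance_to_loci(loci, world.genes)
        edges = [0, *boundaries]
        for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
            expected = int(((dist >= lo) & (dist < hi)).sum())
            assert rings.n_genes.iloc[i] == expected


class TestEnrichmentRatio:
    @pytest.mark.parametrize(
        "top,control,expected", [(104, 55, 1.9), (109, 54, 2.0), (77, 77, 1.0)]
    )
    def test_published_and_trivial_ratios(self, top, control, expected):
        assert enrichment_ratio(top, control) == expected

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            enrichment_ratio(10, 0)


class TestDirectSimulationCI:
    def test_no_flagged_genes_gives_null_interval(self):
        null = direct_simulation_ci(np.zeros(1000, dtype=bool), n=300, k=1000, seed=0)
        assert (null.ci_low, null.ci_high) == (0, 0)

    def test_all_flagged_gives_full_interval(self):
        null = direct_simulation_ci(np.ones(1000, dtype=bool), n=300, k=1000, seed=0)
        assert (null.ci_low, null.ci_high) == (300, 300)

    def test_endpoints_near_exact_hypergeometric_quantiles(self):
        flags = np.zeros(6902, dtype=bool)
        flags[:1400] = True
        null = direct_simulation_ci(flags, n=300, k=100_000, seed=3)
        h = hypergeom(6902, 1400, 300)
        assert abs(null.ci_low - h.ppf(0.025)) <= 1
        assert abs(null.ci_high - h.ppf(0.975)) <= 1

    def test_matches_explicit_gene_resampling(self):
        # same null produced by literally drawing gene sets without replacement
        rng = np.random.default_rng(8)
        flags = np.zeros(400, dtype=bool)
        flags[:120] = True
        null = direct_simulation_ci(flags, n=60, k=4000, seed=9)
        explicit = np.array(
            [flags[rng.choice(400, size=60, replace=False)].sum() for _ in range(4000)]
        )
        assert abs(null.counts.mean() - explicit.mean()) < 0.5
        lo, hi = np.percentile(explicit, [2.5, 97.5])
        assert abs(null.ci_low - math.floor(lo)) <= 1
        assert abs(null.ci_high - math.ceil(hi)) <= 1

    def test_oversized_sample_rejected(self):
        with pytest.raises(ValueError):
            direct_simulation_ci(np.zeros(10, dtype=bool), n=11, k=10, seed=0)


class TestSampleControls:
    def test_fixed_seed_reproduces_sample(self):
        universe = [f"g{i}" for i in range(500)]
        assert sample_controls(universe, 50, seed=4) == sample_controls(universe, 50, seed=4)

    def test_exclusion_is_honoured(self):
        universe = [f"g{i}" for i in range(400)]
        exclude = universe[:100]
        picked = sample_controls(universe, 200, seed=1, exclude=exclude)
        assert not set(picked) & set(exclude)

    def test_insufficient_universe_rejected(self):
        with pytest.raises(ValueError):
            sample_controls(["a", "b"], 3, seed=0)

    def test_sample_frequencies_track_universe(self):
        universe = [f"a{i}" for i in range(300)] + [f"b{i}" for i in range(700)]
        rng = np.random.default_rng(2)
        fracs = []
        for _ in range(300):
            picked = sample_controls(universe, 100, seed=rng)
            fracs.append(np.mean([g.startswith("a") for g in picked]))
        assert np.mean(fracs) == pytest.approx(0.3, abs=0.01)


class TestModelSurface:
    def test_fit_detects_planted_coupling(self, sparse_assoc):
        world, loci = sparse_assoc
        model = EnhancerExpressionAssociation(
            loci, world.genes, world.expression, direction="a"
        )
        res = model.fit(k=20_000, seed=0)
        assert res.observed_top_count > res.null.ci_high
        assert res.significant
        assert res.enrichment > 1.0

    def test_summary_mentions_key_estimates(self, sparse_assoc):
        world, loci = sparse_assoc
        res = EnhancerExpressionAssociation(
            loci, world.genes, world.expression, direction="a"
        ).fit(k=5_000, seed=0)
        text = res.summary()
        assert "enrichment ratio" in text
        assert str(res.null.ci_low) in text
        assert "ratio_a_over_b" in text
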
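"""Enhancer-gene expression association with a resampling null.

Genes are categorized by two-condition differential expression (adjusted
p < 0.05, sign of log fold-change), related to enhancer loci through
TSS-to-midpoint distance windows (20 kb to 2 Mb ladder), and the excess of
enhancer-adjacent differential genes is judged against a direct-simulation
null: random gene sets of the same size drawn from a defined expression
universe, with an empirical 95% confidence interval on the adjacent-gene
count.

The :class:`EnhancerExpressionAssociation` model wraps these operations in a
fit/results object with a printable summary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval
from .stats import ContingencyTable2x2, TestResult, chi_square_2x2

__all__ = [
    "DEFAULT_WINDOWS",
    "GeneCategory",
    "WindowScanResult",
    "NullDistribution",
    "categorize_genes",
    "top_differential",
    "define_universe",
    "genes_within_window",
    "window_scan",
    "interval_scan",
    "enrichment_ratio",
    "direct_simulation_ci",
    "sample_controls",
    "EnhancerExpressionAssociation",
    "AssociationResults",
]

DEFAULT_WINDOWS = (
    20_000,
    50_000,
    100_000,
    250_000,
    500_000,
    750_000,
    1_000_000,
    2_000_000,
)

OVER_A = "over_a"
OVER_B = "over_b"
UNCHANGED = "unchanged"
GeneCategory = str


def _check_expression(expression: pd.DataFrame) -> pd.DataFrame:
    required = {"gene_id", "log_fc", "adj_p"}
    missing = required - set(expression.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    if expression["gene_id"].duplicated().any():
        dup = expression.loc[expression["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id in expression table: {dup!r}")
    return expression


def categorize_genes(expression: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Three-way gene partition: over_a / over_b / unchanged.

    A gene is over-expressed in a cell type iff its adjusted p-value is
    strictly below ``alpha`` and its log fold-change has the matching sign;
    everything else (including adj_p exactly equal to alpha) is unchanged.
    """
    expression = _check_expression(expression)
    sig = expression["adj_p"] < alpha
    cat = np.where(
        sig & (expression["log_fc"] > 0),
        OVER_A,
        np.where(sig & (expression["log_fc"] < 0), OVER_B, UNCHANGED),
    )
    return pd.Series(cat, index=expression["gene_id"].to_numpy(), name="category")


def top_differential(
    expression: pd.DataFrame,
    n: int = 300,
    direction: str = "a",
    alpha: float = 0.05,
) -> list[str]:
    """Top-N differential genes in one direction, ranked by |log fold-change|.

    Ties break on gene_id for determinism. If fewer than ``n`` genes are
    significant in the requested direction, all of them are returned with a
    warning.
    """
    if direction not in {"a", "b"}:
        raise ValueError("direction must be 'a' or 'b'")
    expression = _check_expression(expression)
    sign = 1.0 if direction == "a" else -1.0
    eligible = expression[
        (expression["adj_p"] < alpha) & (sign * expression["log_fc"] > 0)
    ].copy()
    eligible["abs_fc"] = eligible["log_fc"].abs()
    eligible = eligible.sort_values(
        ["abs_fc", "gene_id"], ascending=[False, True], kind="stable"
    )
    if len(eligible) < n:
        warnings.warn(
            f"only {len(eligible)} significant genes in direction {direction!r}; "
            f"requested {n}",
            stacklevel=2,
        )
    return eligible["gene_id"].head(n).tolist()


def define_universe(expression: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """The control universe: differential genes plus genes expressed in both cells.

    Uses the ``expressed_both`` column when present; otherwise every
    non-differential gene counts as expressed in both.
    """
    expression = _check_expression(expression)
    cats = categorize_genes(expression, alpha)
    differential = cats[cats != UNCHANGED].index
    if "expressed_both" in expression.columns:
        both = expression.loc[
            expression["expressed_both"].astype(bool), "gene_id"
        ]
    else:
        both = expression["gene_id"]
    unchanged_both = [g for g in both if cats.get(g) == UNCHANGED]
    return sorted(set(differential) | set(unchanged_both))


def _tss_arrays(genes: Sequence[GeneModel]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    out = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        out[chrom] = (
            np.array([p[0] for p in pairs], dtype=np.int64),
            np.array([p[1] for p in pairs], dtype=object),
        )
    return out


def min_distance_to_loci(
    loci: Sequence[GenomicInterval], genes: Sequence[GeneModel]
) -> pd.Series:
    """Minimal |TSS - locus midpoint| per gene (inf when no locus shares the chromosome)."""
    mids: dict[str, np.ndarray] = {}
    for iv in loci:
        mids.setdefault(iv.chrom, []).append(iv.midpoint)  # type: ignore[union-attr]
    mids = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in mids.items()}
    dist = {}
    for g in genes:
        arr = mids.get(g.chrom)
        if arr is None or arr.size == 0:
            dist[g.gene_id] = math.inf
            continue
        i = int(np.searchsorted(arr, g.tss))
        best = math.inf
        if i > 0:
            best = min(best, abs(g.tss - int(arr[i - 1])))
        if i < arr.size:
            best = min(best, abs(g.tss - int(arr[i])))
        dist[g.gene_id] = float(best)
    return pd.Series(dist, name="min_distance")


def genes_within_window(
    loci: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    window: int,
) -> pd.DataFrame:
    """Genes whose TSS lies strictly within ``window`` bp of any locus midpoint.

    Each gene appears once with its minimal TSS-to-midpoint distance,
    regardless of how many loci fall inside the window.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    dist = min_distance_to_loci(loci, genes)
    hit = dist[dist < window]
    return pd.DataFrame(
        {"gene_id": hit.index.to_numpy(), "min_distance": hit.to_numpy()}
    ).sort_values("gene_id", kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class WindowScanResult:
    window: int
    n_genes: int
    count_over_a: int
    count_over_b: int
    count_unchanged: int
    fraction_over_a: float
    fraction_over_b: float
    fraction_unchanged: float
    ratio_a_over_b: float
    test: TestResult | None = None
    empty: bool = False


def _scan_counts(cats: pd.Series, gene_ids) -> tuple[int, int, int]:
    sub = cats.loc[cats.index.intersection(gene_ids)]
    return (
        int((sub == OVER_A).sum()),
        int((sub == OVER_B).sum()),
        int((sub == UNCHANGED).sum()),
    )


def window_scan(
    loci: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    expression: pd.DataFrame,
    windows: Sequence[int] = DEFAULT_WINDOWS,
    comparison: tuple[int, int] | None = None,
    alpha: float = 0.05,
) -> list[WindowScanResult]:
    """Category composition of genes within each +/-window of the loci.

    ``comparison``, when given, is an (over_a, over_b) count pair from a
    control group; the chi-square contrasts each window's differential counts
    against it.
    """
    if list(windows) != sorted(windows):
        raise ValueError("windows must be ascending")
    cats = categorize_genes(expression, alpha)
    dist = min_distance_to_loci(loci, genes)
    results = []
    for w in windows:
        in_window = dist.index[dist < w]
        n_a, n_b, n_u = _scan_counts(cats, in_window)
        total = n_a + n_b + n_u
        if total == 0:
            results.append(
                WindowScanResult(w, 0, 0, 0, 0, math.nan, math.nan, math.nan, math.nan, None, True)
            )
            continue
        test = None
        if comparison is not None and n_a + n_b > 0 and sum(comparison) > 0:
            test = chi_square_2x2(
                ContingencyTable2x2(n_a, n_b, comparison[0], comparison[1])
            )
        ratio = n_a / n_b if n_b > 0 else math.inf
        results.append(
            WindowScanResult(
                window=w,
                n_genes=total,
                count_over_a=n_a,
                count_over_b=n_b,
                count_unchanged=n_u,
                fraction_over_a=n_a / total,
                fraction_over_b=n_b / total,
                fraction_unchanged=n_u / total,
                ratio_a_over_b=ratio,
                test=test,
            )
        )
    return results


def scan_table(results: Sequence[WindowScanResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "window": [r.window for r in results],
            "n_genes": [r.n_genes for r in results],
            "over_a": [r.count_over_a for r in results],
            "over_b": [r.count_over_b for r in results],
            "unchanged": [r.count_unchanged for r in results],
            "frac_over_a": [r.fraction_over_a for r in results],
            "frac_over_b": [r.fraction_over_b for r in results],
            "frac_unchanged": [r.fraction_unchanged for r in results],
            "ratio_a_over_b": [r.ratio_a_over_b for r in results],
            "p_vs_comparison": [
                r.test.p_value if r.test is not None else math.nan for r in results
            ],
        }
    )


def interval_scan(
    loci: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    expression: pd.DataFrame,
    boundaries: Sequence[int] = DEFAULT_WINDOWS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Category fractions in concentric distance rings around the loci.

    Ring ``i`` holds genes whose minimal distance lies in
    ``[boundaries[i-1], boundaries[i])`` (the first ring starts at 0); each
    gene belongs to exactly one ring.
    """
    if list(boundaries) != sorted(boundaries):
        raise ValueError("boundaries must be ascending")
    cats = categorize_genes(expression, alpha)
    dist = min_distance_to_loci(loci, genes)
    edges = [0, *boundaries]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        ring = dist.index[(dist >= lo) & (dist < hi)]
        n_a, n_b, n_u = _scan_counts(cats, ring)
        total = n_a + n_b + n_u
        rows.append(
            {
                "ring_lo": lo,
                "ring_hi": hi,
                "n_genes": total,
                "over_a": n_a,
                "over_b": n_b,
                "unchanged": n_u,
                "frac_over_a": n_a / total if total else math.nan,
                "frac_over_b": n_b / total if total else math.nan,
                "empty": total == 0,
            }
        )
    return pd.DataFrame(rows)


def enrichment_ratio(count_top: int, count_control: int) -> float:
    """Fold enrichment of an observed count over a control count, one decimal."""
    if count_control <= 0:
        raise ValueError("control count must be positive")
    return round(count_top / count_control, 1)


@dataclass(frozen=True)
class NullDistribution:
    """Empirical null of enhancer-adjacent gene counts from direct simulation."""

    k: int
    counts: np.ndarray
    ci_low: int
    ci_high: int

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low > ci_high")

    def outside(self, observed: int) -> bool:
        return observed < self.ci_low or observed > self.ci_high


def direct_simulation_ci(
    universe_flags: Sequence[bool] | pd.Series,
    n: int = 300,
    k: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> NullDistribution:
    """Null distribution of flagged-gene counts in random size-n gene sets.

    Each replicate draws ``n`` genes without replacement from the universe and
    counts how many carry the flag (an enhancer within the window); the count
    is therefore an exact hypergeometric draw, which is how the replicates are
    generated. The 95% CI is the empirical 2.5th/97.5th percentile
    (linear-interpolation quantiles, rounded outward to integers).
    """
    flags = np.asarray(universe_flags, dtype=bool)
    n_universe = flags.size
    if n > n_universe:
        raise ValueError(f"sample size {n} exceeds universe size {n_universe}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_flagged = int(flags.sum())
    counts = rng.hypergeometric(n_flagged, n_universe - n_flagged, n, size=k)
    lo, hi = np.percentile(counts, [2.5, 97.5], method="linear")
    return NullDistribution(
        k=k,
        counts=counts,
        ci_low=int(math.floor(lo)),
        ci_high=int(math.ceil(hi)),
    )


def sample_controls(
    universe: Sequence[str],
    n: int = 300,
    seed: int | np.random.Generator = 0,
    exclude: Sequence[str] | None = None,
) -> list[str]:
    """Uniform random control gene set from the universe, without replacement."""
    pool = sorted(set(universe) - set(exclude or ()))
    if len(pool) < n:
        raise ValueError(f"universe has {len(pool)} genes after exclusion; need {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    picks = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(picks)]


# --------------------------------------------------------------------------
# model / results surface


class EnhancerExpressionAssociation:
    """Association between one enhancer set and two-condition expression.

    Parameters
    ----------
    loci : enhancer intervals for one cell type (distances anchor at midpoints)
    genes : gene models providing TSS positions
    expression : table with gene_id, log_fc (A - B), adj_p, optional expressed_both
    direction : 'a' if the loci are specific to cell type A, else 'b'
    window : the fixed nearest-enhancer window in bp (default 100 kb)
    windows : the window ladder for the scan
    """

    def __init__(
        self,
        loci: Sequence[GenomicInterval],
        genes: Sequence[GeneModel],
        expression: pd.DataFrame,
        direction: str = "a",
        window: int = 100_000,
        windows: Sequence[int] = DEFAULT_WINDOWS,
        n_top: int = 300,
        alpha: float = 0.05,
    ):
        if direction not in {"a", "b"}:
            raise ValueError("direction must be 'a' or 'b'")
        self.loci = list(loci)
        self.genes = list(genes)
        self.expression = _check_expression(expression)
        self.direction = direction
        self.window = window
        self.windows = tuple(windows)
        self.n_top = n_top
        self.alpha = alpha

    def fit(self, k: int = 100_000, seed: int = 0) -> "AssociationResults":
        """Run the association analysis and the direct-simulation null."""
        rng = np.random.default_rng(seed)
        universe = define_universe(self.expression, self.alpha)
        dist = min_distance_to_loci(self.loci, self.genes)
        flags = pd.Series(
            [dist.get(g, math.inf) < self.window for g in universe], index=universe
        )
        top = top_differential(
            self.expression, n=self.n_top, direction=self.direction, alpha=self.alpha
        )
        observed = int(sum(dist.get(g, math.inf) < self.window for g in top))
        null = direct_simulation_ci(flags.to_numpy(), n=len(top), k=k, seed=rng)
        controls = sample_controls(universe, n=len(top), seed=rng)
        control_count = int(
            sum(dist.get(g, math.inf) < self.window for g in controls)
        )
        ratio = (
            enrichment_ratio(observed, control_count) if control_count > 0 else math.inf
        )
        scan = window_scan(
            self.loci, self.genes, self.expression, self.windows, alpha=self.alpha
        )
        return AssociationResults(
            model=self,
            observed_top_count=observed,
            control_count=control_count,
            enrichment=ratio,
            null=null,
            window_results=scan,
            universe_size=len(universe),
            n_flagged_universe=int(flags.sum()),
        )


@dataclass
class AssociationResults:
    """Estimates and null calibration from a fitted association model."""

    model: EnhancerExpressionAssociation
    observed_top_count: int
    control_count: int
    enrichment: float
    null: NullDistribution
    window_results: list[WindowScanResult]
    universe_size: int
    n_flagged_universe: int

    @property
    def significant(self) -> bool:
        """Observed count outside the 95% simulation CI."""
        return self.null.outside(self.observed_top_count)

    def window_table(self) -> pd.DataFrame:
        return scan_table(self.window_results)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Enhancer-expression association",
            "=" * 47,
            f"direction                 {m.direction}",
            f"loci                      {len(m.loci)}",
            f"genes                     {len(m.genes)}",
            f"universe size             {self.universe_size}",
            f"flagged in universe       {self.n_flagged_universe}",
            f"window (bp)               {m.window}",
            f"top-{m.n_top} observed count    {self.observed_top_count}",
            f"random-control count      {self.control_count}",
            f"enrichment ratio          {self.enrichment}",
            f"null 95% CI (k={self.null.k})   [{self.null.ci_low}, {self.null.ci_high}]",
            f"outside null CI           {self.significant}",
            "",
            self.window_table().to_string(index=False),
        ]
        return "\n".join(lines)
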
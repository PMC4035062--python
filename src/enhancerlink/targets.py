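"""Putative target-gene assignment for active enhancers, and term enrichment.

Genes within the 100 kb windows of both cell types' enhancer sets are
excluded; the remaining exclusive genes are matched to active enhancers of
the concordant cell type (gene overexpressed in that cell, adjusted p < 0.05)
within the window, many-to-many. Gene-set comparisons per ontology term use
the 2x2 chi-square, reported as -log2 p.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import math

import numpy as np
import pandas as pd

from .association import categorize_genes, min_distance_to_loci
from .intervals import GeneModel, GenomicInterval
from .stats import ContingencyTable2x2, chi_square_2x2

__all__ = [
    "TargetAssignment",
    "MultiplicitySummary",
    "exclusive_nearby_genes",
    "assign_targets",
    "multiplicity_summary",
    "category_enrichment",
]

DEFAULT_WINDOW = 100_000


@dataclass(frozen=True)
class TargetAssignment:
    enhancer_id: str
    gene_id: str
    distance: int
    state: str
    concordant: bool


def exclusive_nearby_genes(
    set_a_loci: Sequence[GenomicInterval],
    set_b_loci: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    window: int = DEFAULT_WINDOW,
) -> tuple[list[str], list[str], list[str]]:
    """Partition in-window genes into A-only, B-only and overlapped (excluded).

    A gene is "near" a set when its TSS is strictly within ``window`` bp of
    any locus midpoint of that set; genes near both sets are excluded from
    target assignment.
    """
    if not set_a_loci or not set_b_loci:
        raise ValueError("both locus sets must be non-empty")
    dist_a = min_distance_to_loci(set_a_loci, genes)
    dist_b = min_distance_to_loci(set_b_loci, genes)
    near_a = set(dist_a.index[dist_a < window])
    near_b = set(dist_b.index[dist_b < window])
    return (
        sorted(near_a - near_b),
        sorted(near_b - near_a),
        sorted(near_a & near_b),
    )


def assign_targets(
    active_loci: Sequence[GenomicInterval],
    states: Mapping[str, str],
    exclusive_genes: Sequence[str],
    genes: Sequence[GeneModel],
    expression: pd.DataFrame,
    cell: str = "a",
    window: int = DEFAULT_WINDOW,
    alpha: float = 0.05,
) -> list[TargetAssignment]:
    """Match active enhancers to concordantly overexpressed exclusive genes.

    ``states`` maps locus id to 'active'/'poised'; every supplied locus must
    be active. One assignment is produced per (enhancer, gene) pair within
    the window where the gene is overexpressed in the enhancer's cell type
    (adjusted p < alpha); many-to-many links are allowed.
    """
    if cell not in {"a", "b"}:
        raise ValueError("cell must be 'a' or 'b'")
    for iv in active_loci:
        locus_id = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
        if states.get(locus_id) != "active":
            raise ValueError(f"locus {locus_id!r} is not active")
    cats = categorize_genes(expression, alpha)
    wanted = f"over_{cell}"
    eligible = {
        g for g in exclusive_genes if cats.get(g) == wanted
    }
    gene_models = {g.gene_id: g for g in genes if g.gene_id in eligible}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models.values():
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.tss)
    assignments: list[TargetAssignment] = []
    for iv in active_loci:
        locus_id = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
        mid = iv.midpoint
        for g in by_chrom.get(iv.chrom, ()):
            d = abs(g.tss - mid)
            if d < window:
                assignments.append(
                    TargetAssignment(
                        enhancer_id=locus_id,
                        gene_id=g.gene_id,
                        distance=int(d),
                        state="active",
                        concordant=True,
                    )
                )
    assignments.sort(key=lambda t: (t.enhancer_id, t.gene_id))
    return assignments


@dataclass(frozen=True)
class MultiplicitySummary:
    max_genes_per_enhancer: int
    max_enhancers_per_gene: int
    genes_per_enhancer: dict[int, int]
    enhancers_per_gene: dict[int, int]


def multiplicity_summary(assignments: Sequence[TargetAssignment]) -> MultiplicitySummary:
    """Degree histograms of the enhancer-gene bipartite assignment graph."""
    if not assignments:
        return MultiplicitySummary(0, 0, {}, {})
    per_enh = Counter(a.enhancer_id for a in assignments)
    per_gene = Counter(a.gene_id for a in assignments)
    return MultiplicitySummary(
        max_genes_per_enhancer=max(per_enh.values()),
        max_enhancers_per_gene=max(per_gene.values()),
        genes_per_enhancer=dict(Counter(per_enh.values())),
        enhancers_per_gene=dict(Counter(per_gene.values())),
    )


def category_enrichment(
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    term_map: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term 2x2 chi-square between two gene sets.

    For each term, the table contrasts members vs non-members of the term in
    set A against set B. Terms with no members in either set are skipped;
    rows with p < alpha are returned sorted by ascending p, with -log2 p.
    """
    if "gene_id" not in term_map.columns or "term_id" not in term_map.columns:
        raise ValueError("term_map needs gene_id and term_id columns")
    set_a, set_b = set(genes_a), set(genes_b)
    total_a, total_b = len(set_a), len(set_b)
    if total_a == 0 or total_b == 0:
        raise ValueError("both gene sets must be non-empty")
    members: dict[str, set[str]] = {}
    for row in term_map.itertuples():
        members.setdefault(row.term_id, set()).add(row.gene_id)
    rows = []
    for term in sorted(members):
        in_a = len(members[term] & set_a)
        in_b = len(members[term] & set_b)
        if in_a == 0 and in_b == 0:
            continue
        result = chi_square_2x2(
            ContingencyTable2x2(in_a, total_a - in_a, in_b, total_b - in_b)
        )
        rows.append(
            {
                "term_id": term,
                "count_a": in_a,
                "count_b": in_b,
                "total_a": total_a,
                "total_b": total_b,
                "p_value": result.p_value,
                "neg_log2_p": -math.log2(result.p_value) if result.p_value > 0 else math.inf,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "term_id", "count_a", "count_b", "total_a", "total_b",
            "p_value", "neg_log2_p",
        ],
    )
    if len(df):
        df = df[df["p_value"] < alpha]
        df = df.sort_values(["p_value", "term_id"], kind="stable").reset_index(drop=True)
    return df
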
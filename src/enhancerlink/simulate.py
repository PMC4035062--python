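"""Seeded synthetic data with planted ground truth for the whole pipeline.

The generator emulates the structure of a two-cell-type enhancer study:

* a genome of several chromosomes, each with a gene-rich portion and a
  gene desert, and uniformly placed TSSs;
* cell-type-specific enhancer loci whose H3K4me1 tag density in the matching
  cell exceeds background by a large factor (60x by default), plus shared
  loci enriched in both cells;
* bimodal H3K27Ac: only "active" loci carry acetylation tags;
* nucleosome depletion (FAIRE tags and peaks) at a configured fraction of
  loci of both states;
* gene expression whose probability of cell-type-matched overexpression
  decays exponentially with distance to the nearest specific enhancer;
* region sequences with a consensus motif planted at set-specific rates, and
  a gene->term map with one term biased toward enhancer-coupled genes.

Planted labels live only in ``truth_*`` attributes and are never written
into the pipeline-facing inputs. Identical seeds give identical datasets.
"""

from __future__ import annotations

import math
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from .calling import TagTrack
from .intervals import (
    GeneModel,
    GenomicInterval,
    write_bed,
    write_genes_tsv,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "CapacityError",
    "generate_annotation",
    "generate_tag_tracks",
    "generate_expression",
    "generate_sequences_and_terms",
    "generate_dataset",
]

TRACK_NAMES = (
    "h3k4me1_a",
    "h3k4me1_b",
    "h3k27ac_a",
    "h3k27ac_b",
    "faire_a",
    "faire_b",
)


class CapacityError(RuntimeError):
    """Requested loci cannot be placed with the required separation."""


def _default_chrom_sizes() -> dict[str, int]:
    return {f"chr{i}": 50_000_000 for i in range(1, 5)}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults mirror the study conditions.

    ``coupling(d) = coupling_amp * exp(-d / coupling_scale)`` is the excess
    probability that a gene at distance ``d`` from its nearest specific
    enhancer is overexpressed in the matching cell type, on top of the
    symmetric ``baseline_over`` probability per direction.
    """

    chrom_sizes: dict[str, int] = field(default_factory=_default_chrom_sizes)
    n_genes: int = 6902
    n_specific_enhancers_per_type: int = 2000
    n_shared_enhancers: int = 2000
    n_decoy_loci: int = 1000
    n_decoy_faire: int = 500
    p_active: float = 0.5
    p_faire: float = 0.5
    tss_proximal_fraction: float = 0.7
    coupling_amp: float = 0.5
    coupling_scale: float = 250_000.0
    coupling_shape: str = "exponential"  # or "step": flat excess within coupling_range
    coupling_range: float = 100_000.0
    baseline_over: float = 0.2
    tag_depth: int = 2_000_000
    specific_ratio: float = 60.0
    shared_ratio: float = 20.0
    k27_ratio: float = 30.0
    faire_ratio: float = 20.0
    peak_shape: int = 150  # triangular half-width, bp
    locus_width: int = 1000
    min_separation: int = 1000
    genic_fraction: float = 0.6
    region_length: int = 500
    motif_consensus: str = "TGACTCA"
    motif_rate_pair: tuple[float, float] = (0.4, 0.05)
    term_enriched: str = "GO:ENH_A"
    term_enriched_prob: float = 0.35
    term_background_prob: float = 0.05
    n_background_terms: int = 15
    terms_per_gene: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_active",
            "p_faire",
            "tss_proximal_fraction",
            "coupling_amp",
            "baseline_over",
            "term_enriched_prob",
            "term_background_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not all(0.0 <= r <= 1.0 for r in self.motif_rate_pair):
            raise ValueError("motif rates must be in [0, 1]")
        if self.tag_depth <= 0:
            raise ValueError("tag_depth must be positive")
        if self.coupling_shape not in {"exponential", "step"}:
            raise ValueError(f"unknown coupling_shape {self.coupling_shape!r}")
        if 2 * self.baseline_over > 1.0:
            raise ValueError("baseline_over too large: categories exceed unit mass")

    @property
    def genome_size(self) -> int:
        return sum(self.chrom_sizes.values())

    def coupling_excess(self, d: float) -> float:
        """Excess matched-overexpression probability at distance d (bp)."""
        if self.coupling_shape == "step":
            return self.coupling_amp if d < self.coupling_range else 0.0
        return self.coupling_amp * math.exp(-d / self.coupling_scale)

    def coupling_prob(self, d: float) -> float:
        """Total probability of matched overexpression at distance d (bp)."""
        return min(1.0, self.coupling_excess(d) + self.baseline_over)

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), stream])


@dataclass
class SyntheticDataset:
    """A fully generated world: pipeline inputs plus hidden truth labels."""

    config: SyntheticConfig
    genes: list[GeneModel]
    truth_enhancers: pd.DataFrame
    tag_tracks: dict[str, TagTrack] = field(default_factory=dict)
    expression: pd.DataFrame | None = None
    truth_genes: pd.DataFrame | None = None
    sequences: dict[str, dict[str, str]] = field(default_factory=dict)
    term_map: pd.DataFrame | None = None

    # --- pipeline-facing views (no truth labels) -------------------------
    def enhancer_intervals(self, cell: str | None = None) -> list[GenomicInterval]:
        df = self.truth_enhancers
        if cell is not None:
            df = df[df["cell"] == cell]
        return [
            GenomicInterval(r.chrom, r.start, r.end, name=r.name)
            for r in df.itertuples()
        ]

    @property
    def candidate_loci(self) -> list[GenomicInterval]:
        """All planted loci plus background decoys, stripped of truth labels."""
        return sorted(
            self.enhancer_intervals(), key=GenomicInterval.sort_key
        )

    def faire_peaks(self, cell: str) -> list[GenomicInterval]:
        df = self.truth_enhancers
        mask = df["faire"] & df["cell"].isin([cell, "shared"])
        peaks = [
            GenomicInterval(r.chrom, max(r.midpoint - 200, 0), r.midpoint + 200)
            for r in df[mask].itertuples()
        ]
        rng = self.config._rng(40 if cell == "a" else 41)
        peaks.extend(_random_windows(self.config, rng, self.config.n_decoy_faire, 400))
        return sorted(peaks, key=GenomicInterval.sort_key)

    def write(self, outdir: str | Path) -> None:
        """Write pipeline inputs (BED/TSV/FASTA) and, separately, truth tables."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genes_tsv(outdir / "genes.tsv", self.genes)
        write_bed(outdir / "candidate_loci.bed", self.candidate_loci)
        for cell in ("a", "b"):
            write_bed(outdir / f"faire_peaks_{cell}.bed", self.faire_peaks(cell))
        for name, track in self.tag_tracks.items():
            ivs = [
                GenomicInterval(chrom, int(p), int(p) + 1)
                for chrom, pos in track.positions.items()
                for p in pos
            ]
            write_bed(outdir / f"tags_{name}.bed", ivs)
        if self.expression is not None:
            self.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
        if self.term_map is not None:
            self.term_map.to_csv(outdir / "term_map.tsv", sep="\t", index=False)
        for set_name, seqs in self.sequences.items():
            with open(outdir / f"regions_{set_name}.fasta", "w") as fh:
                for name, seq in seqs.items():
                    fh.write(f">{name}\n{seq}\n")
        self.truth_enhancers.to_csv(outdir / "truth_enhancers.tsv", sep="\t", index=False)
        if self.truth_genes is not None:
            self.truth_genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        with open(outdir / "config.yaml", "w") as fh:
            cfg = {
                k: (dict(v) if isinstance(v, dict) else list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.config).items()
            }
            yaml.safe_dump(cfg, fh, sort_keys=True)


# --------------------------------------------------------------------------
# placement helpers


class _Placer:
    """Tracks placed midpoints per chromosome, enforcing a minimum separation."""

    def __init__(self, min_separation: int):
        self.min_sep = min_separation
        self._mids: dict[str, list[int]] = {}

    def try_place(self, chrom: str, mid: int) -> bool:
        mids = self._mids.setdefault(chrom, [])
        i = bisect_left(mids, mid)
        if i > 0 and mid - mids[i - 1] < self.min_sep:
            return False
        if i < len(mids) and mids[i] - mid < self.min_sep:
            return False
        insort(mids, mid)
        return True


def _random_windows(
    config: SyntheticConfig, rng: np.random.Generator, n: int, width: int
) -> list[GenomicInterval]:
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    out = []
    choices = rng.choice(len(chroms), size=n, p=probs)
    for i in range(n):
        chrom = chroms[choices[i]]
        mid = int(rng.integers(width, config.chrom_sizes[chrom] - width))
        out.append(GenomicInterval(chrom, mid - width // 2, mid + width // 2))
    return out


def generate_annotation(
    config: SyntheticConfig,
) -> tuple[list[GeneModel], pd.DataFrame]:
    """Place genes and planted enhancer loci; deterministic per seed.

    TSSs are uniform (with random strand) in the gene-rich portion of each
    chromosome; ``tss_proximal_fraction`` of specific enhancers are placed
    within 100 kb of a TSS and the remainder in gene deserts. All locus
    midpoints are at least ``min_separation`` bp apart.
    """
    rng = config._rng(0)
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    placer = _Placer(config.min_separation)

    # --- genes ---
    genes: list[GeneModel] = []
    tss_by_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    if config.n_genes > 0:
        gene_chroms = rng.choice(len(chroms), size=config.n_genes, p=probs)
        for i in range(config.n_genes):
            chrom = chroms[gene_chroms[i]]
            limit = int(config.chrom_sizes[chrom] * config.genic_fraction)
            tss = int(rng.integers(60_000, max(limit, 120_000)))
            strand = "+" if rng.random() < 0.5 else "-"
            span = int(rng.integers(2_000, 50_000))
            if strand == "+":
                start, end = tss, tss + span
            else:
                start, end = tss - span + 1, tss + 1
            n_ex = int(rng.integers(2, 6))
            ex_starts = np.sort(rng.integers(start, end - 200, size=n_ex))
            exons, prev_end = [], start - 1
            for es in ex_starts:
                es = max(int(es), prev_end)
                ee = min(es + 200, end)
                if es < ee:
                    exons.append(GenomicInterval(chrom, es, ee))
                    prev_end = ee
            genes.append(
                GeneModel(f"gene_{i:05d}", chrom, start, end, strand, tuple(exons))
            )
            tss_by_chrom[chrom].append(tss)
    for lst in tss_by_chrom.values():
        lst.sort()

    # --- enhancers ---
    half = config.locus_width // 2
    rows = []

    def _place(kind: str, count: int, near_tss: bool | None) -> None:
        max_attempts = 200 * max(count, 1)
        placed = attempts = 0
        while placed < count:
            attempts += 1
            if attempts > max_attempts:
                raise CapacityError(
                    f"could not place {count} {kind} loci with separation "
                    f"{config.min_separation} bp (placed {placed})"
                )
            want_near = (
                near_tss
                if near_tss is not None
                else None
            )
            if want_near is None:
                draw_near = False
            else:
                draw_near = want_near
            if draw_near and any(tss_by_chrom.values()):
                chrom = chroms[int(rng.choice(len(chroms), p=probs))]
                if not tss_by_chrom[chrom]:
                    continue
                tss = int(rng.choice(tss_by_chrom[chrom]))
                offset = int(rng.integers(1_000, 100_000)) * (1 if rng.random() < 0.5 else -1)
                mid = tss + offset
            elif want_near is False and config.n_genes > 0:
                # gene desert: beyond the genic portion plus a 100 kb buffer
                chrom = chroms[int(rng.choice(len(chroms), p=probs))]
                lo = int(config.chrom_sizes[chrom] * config.genic_fraction) + 100_000
                hi = config.chrom_sizes[chrom] - half - 1
                if lo >= hi:
                    continue
                mid = int(rng.integers(lo, hi))
            else:
                chrom = chroms[int(rng.choice(len(chroms), p=probs))]
                mid = int(rng.integers(half + 1, config.chrom_sizes[chrom] - half - 1))
            if mid - half < 0 or mid + half > config.chrom_sizes[chrom]:
                continue
            if not placer.try_place(chrom, mid):
                continue
            rows.append((kind, chrom, mid - half, mid + half))
            placed += 1

    for kind in ("a", "b"):
        n = config.n_specific_enhancers_per_type
        n_near = int(round(n * config.tss_proximal_fraction))
        _place(kind, n_near, near_tss=True)
        _place(kind, n - n_near, near_tss=False)
    _place("shared", config.n_shared_enhancers, near_tss=None)
    _place("decoy", config.n_decoy_loci, near_tss=None)

    df = pd.DataFrame(rows, columns=["cell", "chrom", "start", "end"])
    df["midpoint"] = (df["start"] + df["end"]) // 2
    df["name"] = [f"locus_{i:05d}" for i in range(len(df))]
    is_enh = df["cell"].isin(["a", "b", "shared"])
    df["state"] = np.where(
        is_enh & (rng.random(len(df)) < config.p_active), "active", "poised"
    )
    df.loc[~is_enh, "state"] = "none"
    df["faire"] = is_enh & (rng.random(len(df)) < config.p_faire)
    df = df[["name", "chrom", "start", "end", "midpoint", "cell", "state", "faire"]]
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return genes, df


def generate_tag_tracks(
    config: SyntheticConfig, truth_enhancers: pd.DataFrame
) -> dict[str, TagTrack]:
    """Background-plus-planted tag positions for all six tracks.

    Background tags are uniform over the genome. Each planted locus adds a
    Poisson number of tags (mean = enrichment ratio x expected background in
    the locus window) drawn from a symmetric triangular density around the
    locus midpoint.
    """
    if config.tag_depth <= 0:
        raise ValueError("tag_depth must be positive")
    rng = config._rng(1)
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    bg_window = config.tag_depth * config.locus_width / config.genome_size

    def _enrichment(track: str, row) -> float:
        cell = track[-1]  # 'a' or 'b'
        mark = track[:-2]
        if row.cell == "decoy":
            return 0.0
        if mark == "h3k4me1":
            if row.cell == "shared":
                return config.shared_ratio
            return config.specific_ratio if row.cell == cell else 0.0
        if mark == "h3k27ac":
            if row.state != "active":
                return 0.0
            if row.cell == "shared":
                return config.k27_ratio
            return config.k27_ratio if row.cell == cell else 0.0
        if mark == "faire":
            if not row.faire:
                return 0.0
            if row.cell == "shared":
                return config.faire_ratio
            return config.faire_ratio if row.cell == cell else 0.0
        raise ValueError(track)

    tracks: dict[str, TagTrack] = {}
    for track_name in TRACK_NAMES:
        by_chrom: dict[str, list[np.ndarray]] = {c: [] for c in chroms}
        # background
        counts = rng.multinomial(config.tag_depth, probs)
        for ci, chrom in enumerate(chroms):
            by_chrom[chrom].append(
                rng.integers(0, config.chrom_sizes[chrom], size=counts[ci])
            )
        # planted
        planted_total = 0
        for row in truth_enhancers.itertuples():
            ratio = _enrichment(track_name, row)
            if ratio <= 0:
                continue
            n_extra = rng.poisson(ratio * bg_window)
            if n_extra == 0:
                continue
            offsets = rng.triangular(-config.peak_shape, 0, config.peak_shape, size=n_extra)
            pos = np.clip(
                np.round(row.midpoint + offsets).astype(np.int64),
                0,
                config.chrom_sizes[row.chrom] - 1,
            )
            by_chrom[row.chrom].append(pos)
            planted_total += n_extra
        positions = {
            c: np.sort(np.concatenate(v)) if v else np.array([], dtype=np.int64)
            for c, v in by_chrom.items()
        }
        tracks[track_name] = TagTrack(positions, config.tag_depth + planted_total)
    return tracks


def _nearest_specific(
    truth_enhancers: pd.DataFrame,
) -> dict[str, dict[str, np.ndarray]]:
    out: dict[str, dict[str, np.ndarray]] = {}
    spec = truth_enhancers[truth_enhancers["cell"].isin(["a", "b"])]
    for cell, grp in spec.groupby("cell"):
        out[cell] = {
            chrom: np.sort(sub["midpoint"].to_numpy())
            for chrom, sub in grp.groupby("chrom")
        }
    return out


def _min_distance(mids: np.ndarray, pos: int) -> float:
    if mids.size == 0:
        return math.inf
    i = int(np.searchsorted(mids, pos))
    best = math.inf
    if i > 0:
        best = min(best, abs(pos - int(mids[i - 1])))
    if i < mids.size:
        best = min(best, abs(pos - int(mids[i])))
    return best


def generate_expression(
    config: SyntheticConfig,
    genes: list[GeneModel],
    truth_enhancers: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-condition expression with distance-decaying enhancer coupling.

    Returns ``(expression, truth_genes)``: the pipeline-facing table
    (gene_id, mean_a, mean_b, log_fc, adj_p, expressed_both) and the hidden
    per-gene truth (category, coupling status, nearest enhancer).
    """
    rng = config._rng(2)
    nearest = _nearest_specific(truth_enhancers)
    rows, truth_rows = [], []
    for gene in genes:
        d_a = _min_distance(nearest.get("a", {}).get(gene.chrom, np.array([])), gene.tss)
        d_b = _min_distance(nearest.get("b", {}).get(gene.chrom, np.array([])), gene.tss)
        if d_a <= d_b:
            match_cell, d = "a", d_a
        else:
            match_cell, d = "b", d_b
        coupled = False
        if math.isfinite(d):
            coupled = rng.random() < config.coupling_excess(d)
        if coupled:
            category = f"over_{match_cell}"
        else:
            u = rng.random()
            if u < config.baseline_over:
                category = "over_a"
            elif u < 2 * config.baseline_over:
                category = "over_b"
            else:
                category = "unchanged"
        if category == "unchanged":
            log_fc = float(rng.normal(0.0, 0.1))
            adj_p = float(rng.uniform(0.05, 1.0))
        else:
            magnitude = 0.5 + float(rng.exponential(1.0))
            log_fc = magnitude if category == "over_a" else -magnitude
            adj_p = float(10 ** rng.uniform(-8.0, math.log10(0.049)))
        base = float(2 ** rng.normal(5.0, 1.0))
        mean_a = base * 2 ** (log_fc / 2)
        mean_b = base * 2 ** (-log_fc / 2)
        rows.append((gene.gene_id, mean_a, mean_b, log_fc, adj_p, True))
        truth_rows.append(
            (gene.gene_id, category, coupled, match_cell, d if math.isfinite(d) else -1)
        )
    expression = pd.DataFrame(
        rows, columns=["gene_id", "mean_a", "mean_b", "log_fc", "adj_p", "expressed_both"]
    )
    truth_genes = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "category", "coupled", "nearest_cell", "nearest_dist"],
    )
    return expression, truth_genes


_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def generate_sequences_and_terms(
    config: SyntheticConfig,
    truth_enhancers: pd.DataFrame,
    truth_genes: pd.DataFrame | None = None,
) -> tuple[dict[str, dict[str, str]], pd.DataFrame]:
    """Region sequences with planted motifs, and a biased gene->term map.

    Set A regions are the nucleosome-depleted cell-A-specific loci, set B the
    cell-B counterparts; the consensus is planted once per region (either
    strand) with the set-specific rate. The enriched term is assigned with
    elevated probability to genes coupled to cell-A enhancers.
    """
    motif = config.motif_consensus.upper()
    if len(motif) > config.region_length:
        raise ValueError(
            f"motif length {len(motif)} exceeds region length {config.region_length}"
        )
    rng = config._rng(3)
    sequences: dict[str, dict[str, str]] = {}
    for set_name, cell, rate in (
        ("a", "a", config.motif_rate_pair[0]),
        ("b", "b", config.motif_rate_pair[1]),
    ):
        mask = (truth_enhancers["cell"] == cell) & truth_enhancers["faire"]
        seqs: dict[str, str] = {}
        for row in truth_enhancers[mask].itertuples():
            letters = _BASES[rng.integers(0, 4, size=config.region_length)]
            seq = "".join(letters)
            if rng.random() < rate:
                pos = int(rng.integers(0, config.region_length - len(motif) + 1))
                planted = motif if rng.random() < 0.5 else motif.translate(_COMPLEMENT)[::-1]
                seq = seq[:pos] + planted + seq[pos + len(motif):]
            seqs[row.name] = seq
        sequences[set_name] = seqs

    term_rows = []
    if truth_genes is not None:
        bg_terms = [f"GO:B{i:02d}" for i in range(config.n_background_terms)]
        linked = set(
            truth_genes.loc[
                truth_genes["coupled"] & (truth_genes["nearest_cell"] == "a"), "gene_id"
            ]
        )
        for gene_id in truth_genes["gene_id"]:
            picks = rng.choice(
                config.n_background_terms, size=config.terms_per_gene, replace=False
            )
            for t in picks:
                term_rows.append((gene_id, bg_terms[t]))
            p_enriched = (
                config.term_enriched_prob
                if gene_id in linked
                else config.term_background_prob
            )
            if rng.random() < p_enriched:
                term_rows.append((gene_id, config.term_enriched))
    term_map = pd.DataFrame(term_rows, columns=["gene_id", "term_id"])
    return sequences, term_map


def generate_dataset(
    config: SyntheticConfig | None = None,
    with_tags: bool = True,
    **overrides,
) -> SyntheticDataset:
    """Generate a complete synthetic world from a config (or keyword overrides)."""
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    genes, truth = generate_annotation(config)
    dataset = SyntheticDataset(config=config, genes=genes, truth_enhancers=truth)
    if with_tags:
        dataset.tag_tracks = generate_tag_tracks(config, truth)
    dataset.expression, dataset.truth_genes = generate_expression(config, genes, truth)
    dataset.sequences, dataset.term_map = generate_sequences_and_terms(
        config, truth, dataset.truth_genes
    )
    return dataset
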
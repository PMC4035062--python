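"""Cell-type-specific and shared enhancer calling from two-condition tag data.

Candidate loci (externally called peaks) are quantified in both cell types,
tested for differential H3K4me1 tag density with a library-ratio Poisson test
under Benjamini-Hochberg control, and ranked by fold-change. The top-N loci
per direction form the cell-type-specific enhancer sets; loci with similar
density in both cells form the shared (null-comparison) set.

Normalization is tags per 1e7 sequenced tags; fold-change adds a one-tag
pseudocount to the raw counts before normalization so that empty windows are
defined and the statistic is invariant under joint rescaling of the two
library sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .intervals import GenomicInterval
from .stats import bh_adjust

__all__ = [
    "TagTrack",
    "EnhancerCandidate",
    "EnhancerSet",
    "count_tags",
    "differential_loci",
    "select_top_specific",
    "select_shared",
    "DEFAULT_FLANK",
    "DEFAULT_FDR",
]

DEFAULT_FLANK = 500  # bp either side of the locus midpoint
DEFAULT_FDR = 0.001  # the 0.10% FDR gate
NORM_SCALE = 1e7


@dataclass
class TagTrack:
    """Sorted sequencing-tag positions per chromosome with a library size."""

    positions: dict[str, np.ndarray]
    library_size: int

    def __post_init__(self) -> None:
        clean = {}
        n_stored = 0
        for chrom, pos in self.positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.size and np.any(np.diff(arr) < 0):
                arr = np.sort(arr)
            clean[chrom] = arr
            n_stored += arr.size
        self.positions = clean
        if self.library_size < n_stored:
            raise ValueError(
                f"library_size {self.library_size} < stored tag count {n_stored}"
            )

    @property
    def n_tags(self) -> int:
        return int(sum(arr.size for arr in self.positions.values()))

    @property
    def extent(self) -> int:
        """Approximate genome extent covered by the track (sum of max positions)."""
        return int(
            sum(int(arr[-1]) + 1 for arr in self.positions.values() if arr.size)
        )

    def expected_background_norm(self, window: int) -> float:
        """Expected normalized tag count in a window under a uniform background."""
        if self.extent == 0:
            return 0.0
        return NORM_SCALE * window / self.extent

    @classmethod
    def from_positions(cls, positions: dict[str, Iterable[int]], library_size: int | None = None):
        pos = {c: np.sort(np.asarray(list(p), dtype=np.int64)) for c, p in positions.items()}
        n = sum(a.size for a in pos.values())
        return cls(pos, library_size if library_size is not None else n)

    @classmethod
    def from_bed(cls, path: str | Path, library_size: int | None = None) -> "TagTrack":
        """Load tag positions from a BED file of single-position tags (midpoints used)."""
        from .intervals import read_bed

        by_chrom: dict[str, list[int]] = {}
        for iv in read_bed(path):
            by_chrom.setdefault(iv.chrom, []).append(iv.midpoint)
        return cls.from_positions(by_chrom, library_size)


@dataclass(frozen=True)
class EnhancerCandidate:
    """A candidate locus with raw/normalized counts and differential statistics."""

    interval: GenomicInterval
    tags_a: int
    tags_b: int
    norm_a: float
    norm_b: float
    log2_fc: float
    p_diff: float
    fdr: float

    def __post_init__(self) -> None:
        if self.tags_a < 0 or self.tags_b < 0:
            raise ValueError("tag counts must be non-negative")


@dataclass
class EnhancerSet:
    label: str
    loci: list[EnhancerCandidate] = field(default_factory=list)

    def intervals(self) -> list[GenomicInterval]:
        return [c.interval for c in self.loci]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [c.interval.chrom for c in self.loci],
                "start": [c.interval.start for c in self.loci],
                "end": [c.interval.end for c in self.loci],
                "name": [c.interval.name for c in self.loci],
                "tags_a": [c.tags_a for c in self.loci],
                "tags_b": [c.tags_b for c in self.loci],
                "norm_a": [c.norm_a for c in self.loci],
                "norm_b": [c.norm_b for c in self.loci],
                "log2_fc": [c.log2_fc for c in self.loci],
                "p_diff": [c.p_diff for c in self.loci],
                "fdr": [c.fdr for c in self.loci],
            }
        )


def count_tags(
    track: TagTrack, loci: Sequence[GenomicInterval], flank: int = DEFAULT_FLANK
) -> np.ndarray:
    """Tags in [midpoint - flank, midpoint + flank) per locus (binary search)."""
    if flank <= 0:
        raise ValueError(f"flank must be positive, got {flank}")
    counts = np.zeros(len(loci), dtype=np.int64)
    for i, locus in enumerate(loci):
        pos = track.positions.get(locus.chrom)
        if pos is None or pos.size == 0:
            continue
        mid = locus.midpoint
        lo = np.searchsorted(pos, mid - flank, side="left")
        hi = np.searchsorted(pos, mid + flank, side="left")
        counts[i] = hi - lo
    return counts


def _poisson_two_sided(k: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Two-sided Poisson p-value: 2 * min(lower tail, upper tail), capped at 1."""
    k = np.asarray(k, dtype=float)
    mu = np.asarray(mu, dtype=float)
    lower = _sps.poisson.cdf(k, mu)
    upper = _sps.poisson.sf(k - 1, mu)  # P(X >= k)
    p = 2.0 * np.minimum(lower, upper)
    # mu == 0 is a degenerate null: any observed tag is impossible under it
    p = np.where(mu == 0, np.where(k > 0, 0.0, 1.0), p)
    return np.minimum(p, 1.0)


def differential_loci(
    track_a: TagTrack,
    track_b: TagTrack,
    loci: Sequence[GenomicInterval],
    flank: int = DEFAULT_FLANK,
) -> list[EnhancerCandidate]:
    """Quantify and test every locus for differential tag density.

    Counts in both tracks are normalized to tags per 1e7; the p-value is a
    two-sided Poisson test of ``tags_a`` against ``tags_b`` rescaled by the
    library-size ratio, and the ``fdr`` field is its Benjamini-Hochberg
    adjustment across the supplied loci.
    """
    if track_a.library_size <= 0 or track_b.library_size <= 0:
        raise ValueError("library sizes must be positive")
    tags_a = count_tags(track_a, loci, flank)
    tags_b = count_tags(track_b, loci, flank)
    norm_a = tags_a * (NORM_SCALE / track_a.library_size)
    norm_b = tags_b * (NORM_SCALE / track_b.library_size)
    # pseudocount of one raw tag before normalization keeps the fold-change
    # invariant under joint rescaling of both library sizes
    log2_fc = np.log2(
        ((tags_a + 1.0) / track_a.library_size) / ((tags_b + 1.0) / track_b.library_size)
    )
    ratio = track_a.library_size / track_b.library_size
    p = _poisson_two_sided(tags_a, tags_b * ratio)
    fdr = bh_adjust(p)
    return [
        EnhancerCandidate(
            interval=loci[i],
            tags_a=int(tags_a[i]),
            tags_b=int(tags_b[i]),
            norm_a=float(norm_a[i]),
            norm_b=float(norm_b[i]),
            log2_fc=float(log2_fc[i]),
            p_diff=float(p[i]),
            fdr=float(fdr[i]),
        )
        for i in range(len(loci))
    ]


def select_top_specific(
    candidates: Sequence[EnhancerCandidate],
    n: int = 2000,
    direction: str = "a",
    fdr: float = DEFAULT_FDR,
    label: str | None = None,
) -> EnhancerSet:
    """Top-N cell-type-specific loci, ranked by fold-change among FDR-passing loci.

    ``direction='a'`` selects loci enriched in cell type A (positive log2
    fold-change), ``'b'`` the converse. Ties break on the larger normalized
    count in the favoured cell, then on coordinate order, so selection is
    fully deterministic.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if direction not in {"a", "b"}:
        raise ValueError("direction must be 'a' or 'b'")
    sign = 1.0 if direction == "a" else -1.0
    eligible = [
        c for c in candidates if c.fdr <= fdr and sign * c.log2_fc > 0
    ]
    eligible.sort(
        key=lambda c: (
            -sign * c.log2_fc,
            -(c.norm_a if direction == "a" else c.norm_b),
            c.interval.sort_key(),
        )
    )
    if len(eligible) < n:
        warnings.warn(
            f"only {len(eligible)} candidates pass the FDR {fdr:g} gate in "
            f"direction {direction!r}; requested {n}",
            stacklevel=2,
        )
    chosen = eligible[:n]
    return EnhancerSet(label or f"specific_{direction}", chosen)


def select_shared(
    track_a: TagTrack,
    track_b: TagTrack,
    loci: Sequence[GenomicInterval],
    n: int = 2000,
    flank: int = DEFAULT_FLANK,
    background_norm: float | None = None,
    background_factor: float = 2.0,
) -> EnhancerSet:
    """Shared enhancer loci: similar, above-background density in both cell types.

    Eligible loci have normalized counts above background in *both* cells;
    they are ranked by ascending |log2 fold-change| and the first ``n``
    returned. ``background_norm`` (tags per 1e7) may be given explicitly;
    by default it is ``background_factor`` times the expected uniform
    background per window estimated from each track's extent and depth.
    """
    candidates = differential_loci(track_a, track_b, loci, flank)
    if background_norm is not None:
        bg_a = bg_b = background_norm
    else:
        bg_a = background_factor * track_a.expected_background_norm(2 * flank)
        bg_b = background_factor * track_b.expected_background_norm(2 * flank)
    eligible = [c for c in candidates if c.norm_a > bg_a and c.norm_b > bg_b]
    eligible.sort(key=lambda c: (abs(c.log2_fc), c.interval.sort_key()))
    if len(eligible) < n:
        warnings.warn(
            f"only {len(eligible)} loci exceed background in both cells; requested {n}",
            stacklevel=2,
        )
    return EnhancerSet("shared", eligible[:n])
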
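"""Enhancer state classification and nucleosome-depletion flagging.

Loci are summarized as binned, library-normalized tag-density matrices
(metaplot/heatmap input), classified poised vs active by optimal
one-dimensional 2-means clustering of H3K27Ac density in +/-1 kb of the
midpoint, and flagged as nucleosome-depleted when they intersect a FAIRE
peak within +/-500 bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calling import NORM_SCALE, TagTrack, count_tags
from .intervals import GenomicInterval, merge_intervals

__all__ = [
    "SignalMatrix",
    "EnhancerState",
    "DegenerateClusteringError",
    "build_signal_matrix",
    "mean_profile",
    "kmeans_1d_two",
    "classify_poised_active",
    "faire_flag",
]


class DegenerateClusteringError(ValueError):
    """All features identical: a two-cluster split is undefined."""


@dataclass
class SignalMatrix:
    """Loci x bins matrix of normalized tag densities around locus midpoints."""

    locus_ids: list[str]
    bin_size: int
    window: int
    values: np.ndarray

    def __post_init__(self) -> None:
        expected_bins = 2 * self.window // self.bin_size
        if self.values.shape != (len(self.locus_ids), expected_bins):
            raise ValueError(
                f"values shape {self.values.shape} != ({len(self.locus_ids)}, {expected_bins})"
            )
        if np.any(self.values < 0):
            raise ValueError("tag densities must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        offsets = np.arange(-self.window, self.window, self.bin_size)
        cols = [f"bin_{o}" for o in offsets]
        return pd.DataFrame(self.values, index=self.locus_ids, columns=cols)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="locus")


@dataclass(frozen=True)
class EnhancerState:
    locus_id: str
    state: str  # 'poised' or 'active'
    k27_feature: float
    faire: bool = False


def _locus_ids(loci: Sequence[GenomicInterval]) -> list[str]:
    return [
        iv.name if iv.name else f"{iv.chrom}:{iv.start}-{iv.end}" for iv in loci
    ]


def build_signal_matrix(
    track: TagTrack,
    loci: Sequence[GenomicInterval],
    window: int = 2000,
    bin_size: int = 100,
) -> SignalMatrix:
    """Binned normalized tag counts in [midpoint - window, midpoint + window)."""
    if window % bin_size != 0:
        raise ValueError(f"window {window} must be a multiple of bin_size {bin_size}")
    n_bins = 2 * window // bin_size
    values = np.zeros((len(loci), n_bins))
    scale = NORM_SCALE / track.library_size
    for i, locus in enumerate(loci):
        pos = track.positions.get(locus.chrom)
        if pos is None or pos.size == 0:
            continue
        edges = locus.midpoint - window + bin_size * np.arange(n_bins + 1)
        idx = np.searchsorted(pos, edges, side="left")
        values[i] = np.diff(idx) * scale
    return SignalMatrix(_locus_ids(loci), bin_size, window, values)


def mean_profile(matrix: SignalMatrix) -> np.ndarray:
    """Per-bin mean density across loci (the metaplot line)."""
    if matrix.values.shape[0] == 0:
        raise ValueError("signal matrix has no loci")
    return matrix.values.mean(axis=0)


def kmeans_1d_two(features: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Globally optimal two-cluster 1-D k-means.

    Sorts the features and scans every split point, minimizing within-cluster
    sum of squares with prefix sums; this finds the exact optimum that Lloyd
    iteration only approaches, and is deterministic with no seed. Returns
    (labels in {0 low, 1 high}, low-cluster mean, high-cluster mean).
    """
    x = np.asarray(features, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 features to form two clusters")
    if np.all(x == x[0]):
        raise DegenerateClusteringError("all features identical; two clusters undefined")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    csum = np.cumsum(xs)
    csq = np.cumsum(xs**2)
    n = x.size
    k = np.arange(1, n)  # size of low cluster
    total_sum, total_sq = csum[-1], csq[-1]
    low_sum = csum[:-1]
    sse_low = csq[:-1] - low_sum**2 / k
    high_sum = total_sum - low_sum
    sse_high = (total_sq - csq[:-1]) - high_sum**2 / (n - k)
    sse = sse_low + sse_high
    best = int(np.argmin(sse))  # first optimum -> deterministic tie-break
    split = best + 1
    labels_sorted = np.zeros(n, dtype=int)
    labels_sorted[split:] = 1
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    mean_low = float(xs[:split].mean())
    mean_high = float(xs[split:].mean())
    return labels, mean_low, mean_high


def classify_poised_active(
    loci: Sequence[GenomicInterval],
    k27_track: TagTrack,
    flank: int = 1000,
    method: str = "scalar",
    bin_size: int = 100,
    seed: int = 0,
) -> list[EnhancerState]:
    """Split loci into poised/active by 2-means on H3K27Ac density (+/- flank bp).

    ``method='scalar'`` (default) clusters the library-normalized H3K27Ac tag
    count around the locus midpoint with the exact optimal one-dimensional
    2-means; ``method='vector'`` clusters the binned density profile with
    standard k-means (seeded). Either way, the cluster with the higher mean
    summarized density is labelled active.
    """
    if len(loci) < 2:
        raise ValueError("need at least 2 loci to classify")
    features = count_tags(k27_track, loci, flank) * (NORM_SCALE / k27_track.library_size)
    if method == "scalar":
        labels, _, _ = kmeans_1d_two(features)
    elif method == "vector":
        from sklearn.cluster import KMeans

        matrix = build_signal_matrix(k27_track, loci, window=flank, bin_size=bin_size)
        if np.allclose(matrix.values, matrix.values[0]):
            raise DegenerateClusteringError("identical profiles; two clusters undefined")
        km = KMeans(n_clusters=2, n_init=10, random_state=seed)
        raw = km.fit_predict(matrix.values)
        # relabel so cluster 1 is the one with higher mean summarized density
        mean0 = features[raw == 0].mean()
        mean1 = features[raw == 1].mean()
        labels = raw if mean1 >= mean0 else 1 - raw
    else:
        raise ValueError(f"unknown method {method!r}")
    ids = _locus_ids(loci)
    return [
        EnhancerState(
            locus_id=ids[i],
            state="active" if labels[i] == 1 else "poised",
            k27_feature=float(features[i]),
        )
        for i in range(len(loci))
    ]


def faire_flag(
    loci: Sequence[GenomicInterval],
    faire_peaks: Sequence[GenomicInterval],
    slop: int = 500,
) -> np.ndarray:
    """True per locus iff the locus +/- slop overlaps any FAIRE peak by >= 1 bp."""
    flags = np.zeros(len(loci), dtype=bool)
    if len(faire_peaks) == 0:
        return flags
    merged = merge_intervals(faire_peaks)
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for iv in merged:
        starts.setdefault(iv.chrom, []).append(iv.start)  # type: ignore[union-attr]
        ends.setdefault(iv.chrom, []).append(iv.end)  # type: ignore[union-attr]
    starts = {c: np.array(v) for c, v in starts.items()}
    ends = {c: np.array(v) for c, v in ends.items()}
    for i, locus in enumerate(loci):
        s = starts.get(locus.chrom)
        if s is None:
            continue
        q_start = max(locus.start - slop, 0)
        q_end = locus.end + slop
        j = int(np.searchsorted(s, q_end, side="left"))
        flags[i] = j > 0 and ends[locus.chrom][j - 1] > q_start
    return flags


def state_table(
    states: Sequence[EnhancerState], path: str | Path | None = None
) -> pd.DataFrame:
    """Tidy state table (locus, state, k27_feature, faire); optionally written as TSV."""
    df = pd.DataFrame(
        {
            "locus": [s.locus_id for s in states],
            "state": [s.state for s in states],
            "k27_feature": [s.k27_feature for s in states],
            "faire": [s.faire for s in states],
        }
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
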
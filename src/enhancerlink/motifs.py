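"""PWM motif scanning with exact score-distribution thresholds and enrichment.

Position frequency matrices (JASPAR or minimal MEME text) are converted to
log-odds position weight matrices; the score threshold for a target p-value
(FIMO-style, default 1e-4) comes from the exact distribution of scores under
a 0-order background, computed by dynamic programming over discretized
per-column score distributions. Region sets are scanned on both strands and
compared motif-by-motif with the 2x2 chi-square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import (
    ContingencyTable2x2,
    DegenerateTableError,
    bh_adjust,
    chi_square_2x2,
)

__all__ = [
    "PositionFrequencyMatrix",
    "PositionWeightMatrix",
    "ScoreDistribution",
    "MotifHit",
    "read_jaspar",
    "read_meme",
    "pfm_to_pwm",
    "score_distribution",
    "score_threshold",
    "scan_regions",
    "enrichment_table",
]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Base counts (4 x width) over A, C, G, T for one motif."""

    name: str
    counts: np.ndarray
    database: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError(f"counts must be 4 x w with w >= 1, got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("PFM counts must be non-negative")
        if np.any(counts.sum(axis=0) <= 0):
            raise ValueError("every PFM column must have a positive sum")
        object.__setattr__(self, "counts", counts)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @classmethod
    def from_consensus(cls, consensus: str, name: str | None = None, weight: float = 100.0):
        """Degenerate PFM putting nearly all mass on a consensus sequence."""
        counts = np.ones((4, len(consensus)))
        for i, base in enumerate(consensus.upper()):
            counts[_BASE_INDEX[base], i] = weight
        return cls(name or consensus, counts)


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Log2-odds scores (4 x width) with the background used to build them."""

    name: str
    scores: np.ndarray
    background: np.ndarray
    pseudocount: float
    database: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("PWM scores must be finite")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")

    @property
    def width(self) -> int:
        return self.scores.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.scores.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.scores.min(axis=0).sum())


def pfm_to_pwm(
    pfm: PositionFrequencyMatrix,
    background: Sequence[float] | None = None,
    pseudocount: float = 0.1,
) -> PositionWeightMatrix:
    """Standard log2-odds construction with a background-weighted pseudocount.

    score(b, i) = log2( (count(b,i) + pc * bg_b) / (colsum_i + pc) / bg_b )
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 positive frequencies summing to 1")
    colsums = pfm.counts.sum(axis=0)
    prob = (pfm.counts + pseudocount * bg[:, None]) / (colsums + pseudocount)
    scores = np.log2(prob / bg[:, None])
    return PositionWeightMatrix(
        name=pfm.name,
        scores=scores,
        background=bg,
        pseudocount=pseudocount,
        database=pfm.database,
    )


@dataclass(frozen=True)
class ScoreDistribution:
    """Probability mass of discretized PWM scores under the background model."""

    epsilon: float
    offset: int  # grid index of mass[0]
    mass: np.ndarray

    def __post_init__(self) -> None:
        if abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValueError("score distribution mass must sum to 1")

    def tail(self, score: float) -> float:
        """P(S >= score) on the discretized grid."""
        idx = int(np.ceil(round(score / self.epsilon, 9))) - self.offset
        if idx <= 0:
            return 1.0
        if idx >= self.mass.size:
            return 0.0
        return float(self.mass[idx:].sum())


def score_distribution(
    pwm: PositionWeightMatrix, epsilon: float = 0.01
) -> ScoreDistribution:
    """Exact distribution of window scores under the 0-order background.

    Scores are rounded to an ``epsilon`` grid and the per-column
    distributions convolved position by position (dynamic programme); the
    total discretization error of the threshold is at most width * epsilon.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    grid = np.round(pwm.scores / epsilon).astype(np.int64)
    lo = int(grid.min(axis=0).sum())
    hi = int(grid.max(axis=0).sum())
    mass = np.zeros(hi - lo + 1)
    # DP over columns; 'cur' spans the reachable partial-sum range
    cur = np.array([1.0])
    cur_lo = 0
    for j in range(pwm.width):
        col_scores = grid[:, j]
        col_lo = int(col_scores.min())
        col_hi = int(col_scores.max())
        nxt = np.zeros(cur.size + (col_hi - col_lo))
        for b in range(4):
            shift = int(col_scores[b]) - col_lo
            nxt[shift : shift + cur.size] += pwm.background[b] * cur
        cur = nxt
        cur_lo += col_lo
    mass[cur_lo - lo : cur_lo - lo + cur.size] = cur
    return ScoreDistribution(epsilon=epsilon, offset=lo, mass=mass)


def score_threshold(
    pwm: PositionWeightMatrix, p: float = 1e-4, epsilon: float = 0.01
) -> float:
    """Smallest achievable score whose upper-tail probability is <= p.

    The threshold is found on the ``epsilon`` grid of the exact DP and then
    relaxed by the maximal per-window discretization error
    (``width * epsilon / 2``) so that continuous window scores are judged
    consistently with the discretized distribution. If even the maximal
    score has tail mass above ``p`` the maximum score is returned with a
    warning.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    dist = score_distribution(pwm, epsilon)
    tail = np.cumsum(dist.mass[::-1])[::-1]
    achievable = dist.mass > 0
    ok = achievable & (tail <= p)
    if not ok.any():
        warnings.warn(
            f"no achievable score of motif {pwm.name!r} has tail <= {p:g}; "
            "returning the maximum score",
            stacklevel=2,
        )
        idx = int(np.nonzero(achievable)[0][-1])
    else:
        idx = int(np.nonzero(ok)[0][0])
    return (idx + dist.offset) * epsilon - 0.5 * epsilon * pwm.width


@dataclass(frozen=True)
class MotifHit:
    region: str
    position: int
    strand: str
    score: float


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _scan_one(codes: np.ndarray, scores: np.ndarray, threshold: float) -> np.ndarray:
    """Window scores >= threshold on one strand; windows containing N masked out."""
    w = scores.shape[1]
    n_windows = codes.size - w + 1
    if n_windows <= 0:
        return np.zeros(0, dtype=bool)
    total = np.zeros(n_windows)
    valid = np.ones(n_windows, dtype=bool)
    safe = np.where(codes < 0, 0, codes)
    for j in range(w):
        window_codes = safe[j : j + n_windows]
        total += scores[window_codes, j]
        valid &= codes[j : j + n_windows] >= 0
    return valid & (total >= threshold)


def scan_regions(
    sequences: Mapping[str, str],
    pwm: PositionWeightMatrix,
    threshold: float,
) -> tuple[dict[str, bool], list[MotifHit]]:
    """Scan regions on both strands; a region is hit if any window scores >= threshold.

    Windows containing N are skipped. Regions shorter than the motif are
    reported unhit with a warning.
    """
    hits: dict[str, bool] = {}
    hit_list: list[MotifHit] = []
    short = []
    for region, seq in sequences.items():
        if len(seq) < pwm.width:
            short.append(region)
            hits[region] = False
            continue
        codes = _encode(seq)
        fwd = _scan_one(codes, pwm.scores, threshold)
        rc_codes = _encode(seq.translate(_COMPLEMENT)[::-1])
        rev = _scan_one(rc_codes, pwm.scores, threshold)
        hits[region] = bool(fwd.any() or rev.any())
        for pos in np.nonzero(fwd)[0]:
            score = float(sum(pwm.scores[codes[pos + j], j] for j in range(pwm.width)))
            hit_list.append(MotifHit(region, int(pos), "+", score))
        for pos in np.nonzero(rev)[0]:
            start = len(seq) - pwm.width - int(pos)
            score = float(
                sum(pwm.scores[rc_codes[pos + j], j] for j in range(pwm.width))
            )
            hit_list.append(MotifHit(region, start, "-", score))
    if short:
        warnings.warn(
            f"{len(short)} region(s) shorter than motif width {pwm.width}; reported unhit",
            stacklevel=2,
        )
    return hits, hit_list


def enrichment_table(
    counts: Mapping[str, tuple[int, int]],
    total_a: int,
    total_b: int,
    alpha: float = 0.05,
    databases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-motif 2x2 chi-square between region sets, filtered at ``alpha``.

    ``counts`` maps motif name to (regions hit in set A, regions hit in set
    B). Rows are sorted by ascending p-value; a BH-adjusted column is
    included for convenience although filtering uses the raw p, matching the
    per-test convention of the analysis.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("set totals must be positive")
    rows = []
    for motif, (count_a, count_b) in counts.items():
        if count_a > total_a or count_b > total_b:
            raise ValueError(f"motif {motif!r}: hit count exceeds set total")
        try:
            result = chi_square_2x2(
                ContingencyTable2x2(count_a, total_a - count_a, count_b, total_b - count_b)
            )
        except DegenerateTableError:
            # hit in no region (or every region) of both sets: untestable
            continue
        rows.append(
            {
                "motif": motif,
                "count_a": count_a,
                "count_b": count_b,
                "total_a": total_a,
                "total_b": total_b,
                "p_value": result.p_value,
                "statistic": result.statistic,
                "database": (databases or {}).get(motif, ""),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "motif", "count_a", "count_b", "total_a", "total_b",
            "p_value", "statistic", "database",
        ],
    )
    if len(df):
        df["p_adj"] = bh_adjust(df["p_value"].to_numpy())
        df = df[df["p_value"] < alpha]
        df = df.sort_values(["p_value", "motif"], kind="stable").reset_index(drop=True)
    else:
        df["p_adj"] = pd.Series(dtype=float)
    return df


# --------------------------------------------------------------------------
# PFM readers


def read_jaspar(path: str | Path) -> list[PositionFrequencyMatrix]:
    """Read JASPAR-format PFMs via Biopython's motif parser."""
    from Bio import motifs as _bio_motifs

    out = []
    with open(path) as fh:
        for m in _bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in ALPHABET], dtype=float)
            name = m.name or m.matrix_id or "motif"
            out.append(PositionFrequencyMatrix(name, counts, database="JASPAR"))
    return out


def read_meme(path: str | Path) -> list[PositionFrequencyMatrix]:
    """Minimal MEME text reader: MOTIF blocks with letter-probability matrices."""
    out: list[PositionFrequencyMatrix] = []
    name: str | None = None
    rows: list[list[float]] = []
    nsites = 20.0

    def _flush() -> None:
        nonlocal name, rows
        if name is not None and rows:
            counts = np.array(rows, dtype=float).T * nsites
            out.append(PositionFrequencyMatrix(name, counts, database="MEME"))
        name, rows = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                _flush()
                parts = line.split()
                name = parts[2] if len(parts) > 2 else parts[1]
            elif line.startswith("letter-probability"):
                if "nsites=" in line:
                    nsites = float(line.split("nsites=")[1].split()[0])
            elif name is not None and line and line[0].isdigit():
                values = [float(x) for x in line.split()]
                if len(values) == 4:
                    rows.append(values)
    _flush()
    return out
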
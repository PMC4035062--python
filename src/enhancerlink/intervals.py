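"""Genomic coordinate types, BED IO, overlap arithmetic and feature annotation.

All coordinates are BED-style: 0-based, half-open [start, end). The midpoint
of an interval is floor((start + end) / 2) and is the anchor used for all
distance calculations in the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "GenomeAnnotation",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_genes_tsv",
    "write_genes_tsv",
    "merge_intervals",
    "overlap_fraction",
    "annotate_locus",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional BED6 metadata."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.name or "")


@dataclass(frozen=True)
class GeneModel:
    """A gene: span, strand, exon structure. The TSS is the 5' end of the span.

    For a + strand gene the TSS is ``start``; for a - strand gene it is
    ``end - 1`` (the last covered base).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[GenomicInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad gene span [{self.start}, {self.end})")
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"exon chrom {ex.chrom} != gene chrom {self.chrom}")
            if ex.start < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = ex.end

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


class BedParseError(ValueError):
    """Malformed BED line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ (tab-separated; name/score/strand honoured when present)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError("fewer than 3 tab-separated fields", lineno)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"non-integer coordinates {fields[1]!r}/{fields[2]!r}", lineno
                ) from None
            if start >= end:
                raise BedParseError(f"start {start} >= end {end}", lineno)
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    raise BedParseError(f"non-numeric score {fields[4]!r}", lineno) from None
            strand = fields[5] if len(fields) > 5 and fields[5] in _STRANDS else "."
            try:
                out.append(GenomicInterval(chrom, start, end, name, score, strand))
            except ValueError as exc:
                raise BedParseError(str(exc), lineno) from None
    return out


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    """Write sorted BED6 (missing name/score written as '.')."""
    rows = sorted(intervals, key=GenomicInterval.sort_key)
    with open(path, "w") as fh:
        for iv in rows:
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


def write_genes_tsv(path: str | Path, genes: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\texon_starts\texon_ends\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            starts = ",".join(str(e.start) for e in g.exons)
            ends = ",".join(str(e.end) for e in g.exons)
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t{starts}\t{ends}\n")


def read_genes_tsv(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for raw in fh:
            f = raw.rstrip("\n").split("\t")
            chrom = f[idx["chrom"]]
            starts = f[idx["exon_starts"]]
            ends = f[idx["exon_ends"]]
            exons = tuple(
                GenomicInterval(chrom, int(s), int(e))
                for s, e in zip(starts.split(","), ends.split(","))
                if s != ""
            )
            genes.append(
                GeneModel(
                    gene_id=f[idx["gene_id"]],
                    chrom=chrom,
                    start=int(f[idx["start"]]),
                    end=int(f[idx["end"]]),
                    strand=f[idx["strand"]],
                    exons=exons,
                )
            )
    return genes


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    for lst in out.values():
        lst.sort(key=lambda iv: (iv.start, iv.end))
    return out


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals per chromosome; metadata dropped."""
    merged: list[GenomicInterval] = []
    for chrom, ivs in sorted(_by_chrom(intervals).items()):
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def overlap_fraction(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> float:
    """Fraction of query intervals overlapping (>= 1 bp) any subject interval."""
    if len(query) == 0:
        raise ValueError("query interval set is empty")
    if len(subject) == 0:
        raise ValueError("subject interval set is empty")
    merged = merge_intervals(subject)
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom, ivs in _by_chrom(merged).items():
        starts[chrom] = np.array([iv.start for iv in ivs])
        ends[chrom] = np.array([iv.end for iv in ivs])
    hit = 0
    for q in query:
        s = starts.get(q.chrom)
        if s is None:
            continue
        j = int(np.searchsorted(s, q.end, side="left"))
        if j > 0 and ends[q.chrom][j - 1] > q.start:
            hit += 1
    return hit / len(query)


class GenomeAnnotation:
    """Indexed gene annotation for midpoint-based feature labelling.

    Feature priority is promoter > exon > intron > intergenic. The promoter
    is a strand-aware window around each TSS, by default (-1000, +100) bp
    relative to the direction of transcription.
    """

    def __init__(
        self,
        genes: Sequence[GeneModel],
        promoter_window: tuple[int, int] = (-1000, 100),
    ):
        up, down = promoter_window
        if up > 0 or down < 0:
            raise ValueError("promoter_window must be (negative upstream, positive downstream)")
        self.genes = list(genes)
        self.promoter_window = (up, down)
        self._promoters: dict[str, IntervalTree] = {}
        self._exons: dict[str, IntervalTree] = {}
        self._spans: dict[str, IntervalTree] = {}
        for g in self.genes:
            if g.strand == "+":
                p_lo, p_hi = g.tss + up, g.tss + down + 1
            else:
                p_lo, p_hi = g.tss - down, g.tss - up + 1
            p_lo = max(p_lo, 0)
            if p_lo < p_hi:
                self._promoters.setdefault(g.chrom, IntervalTree()).addi(p_lo, p_hi, g.gene_id)
            for ex in g.exons:
                self._exons.setdefault(g.chrom, IntervalTree()).addi(ex.start, ex.end, g.gene_id)
            self._spans.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)

    @property
    def chromosomes(self) -> set[str]:
        return set(self._spans)

    def label(self, locus: GenomicInterval) -> str:
        return annotate_locus(locus, self)


def annotate_locus(locus: GenomicInterval, annotation: GenomeAnnotation) -> str:
    """Label a locus as promoter/exon/intron/intergenic by its midpoint.

    A locus on a chromosome absent from the annotation is labelled intergenic
    with a warning.
    """
    if locus.chrom not in annotation.chromosomes:
        warnings.warn(
            f"chromosome {locus.chrom!r} not in annotation; labelling intergenic",
            stacklevel=2,
        )
        return "intergenic"
    mid = locus.midpoint
    if annotation._promoters.get(locus.chrom, IntervalTree()).overlaps_point(mid):
        return "promoter"
    if annotation._exons.get(locus.chrom, IntervalTree()).overlaps_point(mid):
        return "exon"
    if annotation._spans[locus.chrom].overlaps_point(mid):
        return "intron"
    return "intergenic"
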
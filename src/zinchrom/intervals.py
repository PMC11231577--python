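"""Genomic interval model and set operations.

All coordinates are 0-based, half-open ``[start, end)``, the BED convention.
The operations here mirror the interval arithmetic used when assembling
accessible-chromatin regions of interest: merging peak sets across
treatments, removing peaks that touch blacklisted regions, retaining ChIP
peaks by fractional overlap with transcribed regions, and labelling regions
as promoter / genic / nongenic relative to a gene annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "GeneAnnotation",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "merge_regions",
    "subtract_blacklist",
    "intersect_fraction",
    "promoter_interval",
    "annotate_regions",
    "region_center",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval with optional BED6 metadata."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - . , got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def region_center(interval: GenomicInterval) -> int:
    """Center coordinate, ``floor((start + end) / 2)``."""
    return (interval.start + interval.end) // 2


@dataclass
class RegionSet:
    """A sorted, deduplicated collection of :class:`GenomicInterval`.

    Sort key is ``(chrom, start, end)``; duplicate ``(chrom, start, end,
    strand)`` tuples are collapsed to one.
    """

    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, int, str]] = set()
        out: list[GenomicInterval] = []
        for iv in sorted(
            self.intervals, key=lambda r: (r.chrom, r.start, r.end, r.strand)
        ):
            key = (iv.chrom, iv.start, iv.end, iv.strand)
            if key not in seen:
                seen.add(key)
                out.append(iv)
        self.intervals = out

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.intervals == other.intervals

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.intervals],
                "start": [r.start for r in self.intervals],
                "end": [r.end for r in self.intervals],
                "name": [r.name for r in self.intervals],
                "score": [r.score for r in self.intervals],
                "strand": [r.strand for r in self.intervals],
            }
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """Transcription span of one gene; strand determines the promoter side."""

    gene_id: str
    chrom: str
    tx_start: int
    tx_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start must be < tx_end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")


# ---------------------------------------------------------------------------
# I/O


def read_bed(path: str | Path) -> RegionSet:
    """Read a BED3/BED6 file (0-based half-open) into a :class:`RegionSet`."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, name, score, strand)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return RegionSet(intervals)


def write_bed(regions: RegionSet, path: str | Path) -> None:
    """Write BED6, preserving 0-based half-open coordinates."""
    with open(path, "w") as fh:
        for r in regions:
            score = format(r.score, "g")
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{score}\t{r.strand}\n")


def read_gene_table(path: str | Path) -> list[GeneAnnotation]:
    """Read a gene annotation TSV: gene_id, chrom, tx_start, tx_end, strand."""
    df = pd.read_csv(path, sep="\t")
    return [
        GeneAnnotation(str(g.gene_id), str(g.chrom), int(g.tx_start), int(g.tx_end), str(g.strand))
        for g in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Set operations


def merge_regions(sets: Sequence[RegionSet]) -> RegionSet:
    """Union of all input sets with overlapping or book-ended intervals coalesced.

    Book-ended intervals ([0,10) and [10,20)) merge: in half-open coordinates
    adjacency means contiguous chromatin. Names/scores/strands are dropped;
    merged intervals are renamed ``merged_<i>``.
    """
    if not sets:
        raise ValueError("merge_regions requires at least one RegionSet")
    pooled = sorted(
        (iv for s in sets for iv in s), key=lambda r: (r.chrom, r.start, r.end)
    )
    merged: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = None, 0, 0
    out: list[tuple[str, int, int]] = []
    for iv in pooled:
        if iv.chrom == cur_chrom and iv.start <= cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            if cur_chrom is not None:
                out.append((cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    if cur_chrom is not None:
        out.append((cur_chrom, cur_start, cur_end))
    for i, (chrom, start, end) in enumerate(out):
        merged.append(GenomicInterval(chrom, start, end, f"merged_{i}"))
    return RegionSet(merged)


def subtract_blacklist(regions: RegionSet, blacklist: RegionSet) -> RegionSet:
    """Remove (whole-interval, no trimming) any region overlapping the blacklist."""
    bl = blacklist.by_chrom()
    kept = []
    for iv in regions:
        chrom_bl = bl.get(iv.chrom, [])
        if not any(iv.start < b.end and b.start < iv.end for b in chrom_bl):
            kept.append(iv)
    return RegionSet(kept)


def intersect_fraction(a: RegionSet, b: RegionSet, min_frac: float) -> RegionSet:
    """Retain each a-interval covered by the union of b for >= ``min_frac`` of its length.

    The fraction is computed relative to the a-interval (the prose reading of a
    bedtools ``-F 0.5`` ChIP-vs-transcription filter: keep ChIP peaks that
    overlap at least 50%). b is union-merged first so overlapping b-intervals
    are not double counted. Retained a-intervals are returned unmodified.
    """
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    b_merged = merge_regions([b]).by_chrom() if len(b) else {}
    kept = []
    for iv in a:
        cov = sum(iv.overlap_length(x) for x in b_merged.get(iv.chrom, []))
        if cov >= min_frac * len(iv):
            kept.append(iv)
    return RegionSet(kept)


def promoter_interval(gene: GeneAnnotation, promoter_length: int = 1000) -> GenomicInterval | None:
    """Promoter = ``promoter_length`` bp immediately upstream of the TSS.

    For a + strand gene this is [tx_start - L, tx_start); for a - strand gene
    [tx_end, tx_end + L). Promoters extending below coordinate 0 are clipped;
    a promoter fully clipped away returns None.
    """
    if gene.strand == "+":
        start, end = max(0, gene.tx_start - promoter_length), gene.tx_start
    else:
        start, end = gene.tx_end, gene.tx_end + promoter_length
    if start >= end:
        return None
    return GenomicInterval(gene.chrom, start, end, f"{gene.gene_id}_promoter")


def annotate_regions(
    regions: RegionSet,
    genes: Iterable[GeneAnnotation],
    promoter_length: int = 1000,
) -> pd.Series:
    """Label each region promoter / genic / nongenic.

    A region overlapping any promoter is ``promoter`` (promoter takes
    precedence); otherwise a region overlapping any gene body is ``genic``;
    otherwise ``nongenic``. Returns a Series indexed by region name.
    """
    genes = list(genes)
    promoters: dict[str, list[GenomicInterval]] = {}
    bodies: dict[str, list[GenomicInterval]] = {}
    for g in genes:
        p = promoter_interval(g, promoter_length)
        if p is not None:
            promoters.setdefault(g.chrom, []).append(p)
        bodies.setdefault(g.chrom, []).append(
            GenomicInterval(g.chrom, g.tx_start, g.tx_end, g.gene_id)
        )
    labels = {}
    for iv in regions:
        if any(iv.overlaps(p) for p in promoters.get(iv.chrom, [])):
            labels[iv.name] = "promoter"
        elif any(iv.overlaps(b) for b in bodies.get(iv.chrom, [])):
            labels[iv.name] = "genic"
        else:
            labels[iv.name] = "nongenic"
    return pd.Series(labels, name="label")
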
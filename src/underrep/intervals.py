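"""Genomic coordinate types and interval algebra.

All coordinates are 0-based half-open ``[start, end)``, the BED convention.
Any 1-based input is converted at the reader boundary (:mod:`underrep.io`).
Strand is carried on :class:`GenomicInterval` but ignored by the algebra:
every overlap/coverage rule in this package is strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "AnnotationPartition",
    "overlap_length",
    "coverage_fraction",
    "intersect_sets",
    "union_sets",
    "subtract_sets",
    "complement",
    "partition_annotation",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a named chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start : int
        0-based inclusive start, ``>= 0``.
    end : int
        Exclusive end, ``> start``.
    strand : str
        One of ``'+'``, ``'-'``, ``'.'`` (unstranded). Carried, never used
        by the interval algebra.
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of '+', '-', '.', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Integer midpoint, used for length-proportional element assignment."""
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 if different chromosomes).

    Half-open convention: ``[0,10)`` and ``[10,20)`` abut and share 0 bases.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


class RegionSet:
    """An immutable, merged collection of genomic intervals.

    Overlapping and book-ended input intervals on the same chromosome are
    merged at construction, so member intervals are disjoint and sorted by
    ``(chrom, start)`` and coverage sums are well defined.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), name: str = "") -> None:
        self.name = name
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in sorted(by_chrom):
            pairs = sorted(by_chrom[chrom])
            merged: list[list[int]] = []
            for s, e in pairs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            starts = np.fromiter((m[0] for m in merged), dtype=np.int64, count=len(merged))
            ends = np.fromiter((m[1] for m in merged), dtype=np.int64, count=len(merged))
            self._by_chrom[chrom] = (starts, ends)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_arrays(
        cls, chrom_arrays: dict[str, tuple[np.ndarray, np.ndarray]], name: str = ""
    ) -> "RegionSet":
        """Build directly from per-chromosome sorted disjoint start/end arrays."""
        rs = cls((), name=name)
        rs._by_chrom = {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for c, (s, e) in sorted(chrom_arrays.items())
        }
        return rs

    # -- basic queries --------------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self._by_chrom.get(
            chrom, (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        )

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom, (starts, ends) in self._by_chrom.items():
            for s, e in zip(starts.tolist(), ends.tolist()):
                yield GenomicInterval(chrom, s, e)

    def __len__(self) -> int:
        return sum(len(s) for s, _ in self._by_chrom.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        if set(self._by_chrom) != set(other._by_chrom):
            return False
        return all(
            np.array_equal(self._by_chrom[c][0], other._by_chrom[c][0])
            and np.array_equal(self._by_chrom[c][1], other._by_chrom[c][1])
            for c in self._by_chrom
        )

    def total_length(self) -> int:
        return int(sum((e - s).sum() for s, e in self._by_chrom.values()))

    def overlap_length(self, iv: GenomicInterval) -> int:
        """Total bases of ``iv`` covered by this set."""
        starts, ends = self.arrays(iv.chrom)
        if len(starts) == 0:
            return 0
        i = int(np.searchsorted(ends, iv.start, side="right"))
        j = int(np.searchsorted(starts, iv.end, side="left"))
        if j <= i:
            return 0
        return int(
            np.sum(
                np.minimum(ends[i:j], iv.end) - np.maximum(starts[i:j], iv.start)
            )
        )

    def overlaps(self, iv: GenomicInterval) -> bool:
        return self.overlap_length(iv) > 0

    def contains_point(self, chrom: str, pos: int) -> bool:
        """True if base ``pos`` (0-based) lies inside the set."""
        starts, ends = self.arrays(chrom)
        if len(starts) == 0:
            return False
        k = int(np.searchsorted(starts, pos, side="right")) - 1
        return k >= 0 and pos < int(ends[k])


def coverage_fraction(span: GenomicInterval, regions: RegionSet) -> float:
    """Fraction of ``span`` covered by ``regions``, in [0, 1].

    Summed over every region interval, so a span straddling two regions
    counts its combined coverage.
    """
    if span.length <= 0:  # unreachable through GenomicInterval, guards raw use
        raise ValueError("zero-length span has no defined coverage")
    return regions.overlap_length(span) / span.length


def _pairwise_intersect(
    a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray]
) -> list[tuple[int, int]]:
    sa, ea = (x.tolist() for x in a)
    sb, eb = (x.tolist() for x in b)
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(sa) and j < len(sb):
        lo = max(sa[i], sb[j])
        hi = min(ea[i], eb[j])
        if hi > lo:
            out.append((lo, hi))
        if ea[i] < eb[j]:
            i += 1
        else:
            j += 1
    return out


def intersect_sets(a: RegionSet, b: RegionSet, name: str = "") -> RegionSet:
    """Exact base-level intersection of two region sets.

    Commutative and associative, so four pairwise conservation tracks can be
    intersected iteratively in any order.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in a.chroms:
        if chrom not in b.chroms:
            continue
        pieces = _pairwise_intersect(a.arrays(chrom), b.arrays(chrom))
        if pieces:
            arr = np.asarray(pieces, dtype=np.int64)
            out[chrom] = (arr[:, 0], arr[:, 1])
    return RegionSet.from_arrays(out, name=name)


def union_sets(a: RegionSet, b: RegionSet, name: str = "") -> RegionSet:
    return RegionSet(list(a) + list(b), name=name)


def subtract_sets(a: RegionSet, b: RegionSet, name: str = "") -> RegionSet:
    """Bases of ``a`` not covered by ``b``."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in a.chroms:
        sa, ea = a.arrays(chrom)
        sb, eb = b.arrays(chrom)
        sb_l, eb_l = sb.tolist(), eb.tolist()
        pieces: list[tuple[int, int]] = []
        j = 0
        for s, e in zip(sa.tolist(), ea.tolist()):
            cur = s
            while j < len(sb_l) and eb_l[j] <= cur:
                j += 1
            k = j
            while k < len(sb_l) and sb_l[k] < e:
                if sb_l[k] > cur:
                    pieces.append((cur, sb_l[k]))
                cur = max(cur, eb_l[k])
                if cur >= e:
                    break
                k += 1
            if cur < e:
                pieces.append((cur, e))
        if pieces:
            arr = np.asarray(pieces, dtype=np.int64)
            out[chrom] = (arr[:, 0], arr[:, 1])
    return RegionSet.from_arrays(out, name=name)


def complement(regions: RegionSet, chromosomes: Sequence[GenomicInterval], name: str = "") -> RegionSet:
    """Bases of the declared chromosomes not covered by ``regions``."""
    return subtract_sets(RegionSet(chromosomes), regions, name=name)


@dataclass
class AnnotationPartition:
    """Disjoint exonic / intronic / intergenic partition of the genome.

    Precedence is exonic > intronic > intergenic: a base inside an exon of
    any isoform of any locus is exonic even if another isoform or locus
    treats it as intronic. The three sets tile the declared chromosomes
    exactly.
    """

    exonic: RegionSet
    intronic: RegionSet
    intergenic: RegionSet

    def category_of_point(self, chrom: str, pos: int) -> str:
        if self.exonic.contains_point(chrom, pos):
            return "exonic"
        if self.intronic.contains_point(chrom, pos):
            return "intronic"
        return "intergenic"

    def get(self, category: str) -> RegionSet:
        return getattr(self, category)


def partition_annotation(loci, chromosomes: Sequence[GenomicInterval]) -> AnnotationPartition:
    """Partition the declared chromosomes into exonic/intronic/intergenic bases.

    Parameters
    ----------
    loci : sequence of Locus
        Gene models; every exon of every isoform contributes to the exonic
        set, every locus span to the genic set.
    chromosomes : sequence of GenomicInterval
        Full chromosome extents; loci must fall inside them.

    Raises
    ------
    ValueError
        If a locus lies outside the declared chromosome bounds.
    """
    chrom_set = RegionSet(chromosomes)
    exons: list[GenomicInterval] = []
    spans: list[GenomicInterval] = []
    for locus in loci:
        span = locus.span
        if chrom_set.overlap_length(span) != span.length:
            raise ValueError(f"locus {locus.id} at {span} outside declared chromosomes")
        spans.append(span)
        for iso in locus.isoforms:
            exons.extend(iso.exons)
    exonic = RegionSet(exons, name="exonic")
    genic = RegionSet(spans)
    intronic = subtract_sets(genic, exonic, name="intronic")
    intergenic = subtract_sets(chrom_set, genic, name="intergenic")
    return AnnotationPartition(exonic=exonic, intronic=intronic, intergenic=intergenic)
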
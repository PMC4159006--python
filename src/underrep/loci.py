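"""Gene-model (locus) types.

A locus is a gene with one or more transcript isoforms; each isoform carries
its genomic span, exon blocks, and CDS blocks. Conservation/expression
annotations (homology in distant species, testis-specific expression, EST
support, ncRNA class) arrive as label flags from an upstream table — this
package never re-derives homology calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import GenomicInterval, RegionSet

#: recognised boolean label flags on a locus
KNOWN_FLAGS = frozenset(
    {
        "human_homolog",
        "mosquito_homolog",
        "virilis_homolog",
        "testis_specific",
        "est_support",
        "expression_known",
    }
)

#: recognised short/long noncoding RNA classes
NCRNA_CLASSES = ("miRNA", "snoRNA", "tRNA", "lincRNA", "none")


@dataclass(frozen=True)
class Isoform:
    """One transcript isoform: span, exon blocks and CDS blocks (all half-open)."""

    name: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"isoform {self.name} has no exons")
        exon_set = RegionSet(self.exons)
        for ex in self.exons:
            if ex.chrom != self.span.chrom or ex.start < self.span.start or ex.end > self.span.end:
                raise ValueError(f"isoform {self.name}: exon {ex} outside span {self.span}")
        for c in self.cds:
            if exon_set.overlap_length(c) != c.length:
                raise ValueError(f"isoform {self.name}: CDS block {c} not inside exons")

    @property
    def cds_length(self) -> int:
        return sum(c.length for c in self.cds)

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)


@dataclass
class Locus:
    """A gene: isoforms plus annotation labels.

    ``protein_length`` is the amino-acid count of the selected isoform
    (lexicographically first isoform name); ``None`` for noncoding loci.
    """

    id: str
    chrom: str
    isoforms: tuple[Isoform, ...]
    protein_length: int | None = None
    labels: frozenset[str] = frozenset()
    ncrna_class: str = "none"

    def __post_init__(self) -> None:
        if not self.isoforms:
            raise ValueError(f"locus {self.id} has no isoforms")
        if any(iso.span.chrom != self.chrom for iso in self.isoforms):
            raise ValueError(f"locus {self.id}: isoform on a different chromosome")
        unknown = set(self.labels) - KNOWN_FLAGS
        if unknown:
            raise ValueError(f"locus {self.id}: unknown label flags {sorted(unknown)}")
        if self.ncrna_class not in NCRNA_CLASSES:
            raise ValueError(f"locus {self.id}: unknown ncRNA class {self.ncrna_class!r}")
        if self.is_coding and (self.protein_length is None or self.protein_length < 1):
            raise ValueError(f"locus {self.id}: coding locus needs protein_length >= 1")

    @property
    def is_coding(self) -> bool:
        return any(iso.cds for iso in self.isoforms)

    @property
    def span(self) -> GenomicInterval:
        """Minimal interval from the left-most start to the right-most end of all isoforms."""
        return GenomicInterval(
            self.chrom,
            min(iso.span.start for iso in self.isoforms),
            max(iso.span.end for iso in self.isoforms),
            self.isoforms[0].span.strand,
        )

    @property
    def selected_isoform(self) -> Isoform:
        """The single isoform used for protein length and CDS alignment:
        first in alphabetical order of isoform name."""
        return min(self.isoforms, key=lambda iso: iso.name)

    def has(self, flag: str) -> bool:
        return flag in self.labels


def locus_span(locus: Locus) -> GenomicInterval:
    """Minimal genomic interval covering every isoform span of the locus."""
    return locus.span
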
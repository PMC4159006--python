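"""Readers and writers for the plain-text formats the pipeline consumes.

BED (3/5/6/12) and bedGraph are handled natively in the 0-based half-open
convention; per-gene codon alignments are aligned FASTA (one record per
taxon) via Biopython. Gene models use BED12: blocks are exons, the
thickStart/thickEnd range is the CDS, and the name field is
``<locus_id>|<isoform_name>`` so multiple isoforms of a locus group
together.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .divergence import CodonAlignment
from .intervals import GenomicInterval, RegionSet
from .loci import KNOWN_FLAGS, Isoform, Locus
from .scores import ReplicationProbe

_FLAG_COLUMNS = (
    "human_homolog",
    "mosquito_homolog",
    "virilis_homolog",
    "testis_specific",
    "est_support",
    "expression_known",
)


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """BED3/BED6 intervals; strand kept when present, name/score ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) >= 6 and f[5] in "+-" else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(path: str | os.PathLike, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_scored_bed(path: str | os.PathLike) -> list[tuple[GenomicInterval, float]]:
    """BED5 (chrom, start, end, name, score) elements with their scores."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((GenomicInterval(f[0], int(f[1]), int(f[2])), float(f[4])))
    return out


def write_scored_bed(
    path: str | os.PathLike, elements: Iterable[tuple[GenomicInterval, float]]
) -> None:
    with open(path, "w") as fh:
        for k, (iv, score) in enumerate(elements):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\telem{k}\t{score:g}\n")


# ---------------------------------------------------------------------------
# BED12 gene models
# ---------------------------------------------------------------------------


def _split_name(name: str) -> tuple[str, str]:
    if "|" in name:
        gene, iso = name.split("|", 1)
        return gene, iso
    return name, name


def read_bed12_loci(path: str | os.PathLike) -> list[Locus]:
    """Gene models from BED12: blocks = exons, thickStart/thickEnd = CDS.

    Protein length of a coding isoform is CDS length / 3 - 1 (the stop codon
    is inside the CDS range). Label flags are attached separately from the
    label table.
    """
    isoforms_by_gene: dict[str, list[Isoform]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if f[5] in "+-" else "."
            thick_s, thick_e = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ValueError(f"malformed BED12 blocks for {name}")
            exons = tuple(
                GenomicInterval(chrom, start + o, start + o + s, strand)
                for o, s in zip(offsets, sizes)
            )
            cds = tuple(
                GenomicInterval(chrom, max(e.start, thick_s), min(e.end, thick_e), strand)
                for e in exons
                if min(e.end, thick_e) > max(e.start, thick_s)
            )
            gene, iso_name = _split_name(name)
            iso = Isoform(
                name=iso_name,
                span=GenomicInterval(chrom, start, end, strand),
                exons=exons,
                cds=cds,
            )
            if gene not in isoforms_by_gene:
                order.append(gene)
            isoforms_by_gene.setdefault(gene, []).append(iso)
    loci = []
    for gene in order:
        isos = tuple(sorted(isoforms_by_gene[gene], key=lambda i: i.name))
        selected = min(isos, key=lambda i: i.name)
        plen = selected.cds_length // 3 - 1 if selected.cds else None
        loci.append(
            Locus(
                id=gene,
                chrom=isos[0].span.chrom,
                isoforms=isos,
                protein_length=plen if plen and plen >= 1 else (1 if selected.cds else None),
            )
        )
    return loci


def write_bed12_loci(path: str | os.PathLike, loci: Sequence[Locus]) -> None:
    with open(path, "w") as fh:
        for locus in loci:
            for iso in locus.isoforms:
                span = iso.span
                exons = sorted(iso.exons, key=lambda e: e.start)
                if iso.cds:
                    thick_s = min(c.start for c in iso.cds)
                    thick_e = max(c.end for c in iso.cds)
                else:
                    thick_s = thick_e = span.start
                sizes = ",".join(str(e.length) for e in exons) + ","
                offsets = ",".join(str(e.start - span.start) for e in exons) + ","
                fh.write(
                    "\t".join(
                        [
                            span.chrom,
                            str(span.start),
                            str(span.end),
                            f"{locus.id}|{iso.name}",
                            "0",
                            span.strand if span.strand in "+-" else "+",
                            str(thick_s),
                            str(thick_e),
                            "0",
                            str(len(exons)),
                            sizes,
                            offsets,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# label tables
# ---------------------------------------------------------------------------


def read_label_table(path: str | os.PathLike) -> dict[str, tuple[frozenset[str], str]]:
    """Tab-delimited labels: locus_id, one 0/1 column per flag, ncrna_class."""
    out: dict[str, tuple[frozenset[str], str]] = {}
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header[0] != "locus_id":
            raise ValueError("label table must start with a locus_id column")
        flag_cols = [h for h in header[1:] if h in KNOWN_FLAGS]
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rec = dict(zip(header, f))
            flags = frozenset(c for c in flag_cols if rec.get(c, "0") == "1")
            out[rec["locus_id"]] = (flags, rec.get("ncrna_class", "none") or "none")
    return out


def write_label_table(path: str | os.PathLike, loci: Sequence[Locus]) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\t" + "\t".join(_FLAG_COLUMNS) + "\tncrna_class\n")
        for locus in loci:
            flags = "\t".join("1" if locus.has(c) else "0" for c in _FLAG_COLUMNS)
            fh.write(f"{locus.id}\t{flags}\t{locus.ncrna_class}\n")


def apply_labels(loci: Sequence[Locus], table: Mapping[str, tuple[frozenset[str], str]]) -> None:
    """Attach label flags / ncRNA class from a label table, in place."""
    for locus in loci:
        if locus.id in table:
            flags, ncrna = table[locus.id]
            locus.labels = flags
            locus.ncrna_class = ncrna


# ---------------------------------------------------------------------------
# bedGraph probe tracks
# ---------------------------------------------------------------------------


def read_bedgraph(path: str | os.PathLike) -> list[ReplicationProbe]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(ReplicationProbe(GenomicInterval(f[0], int(f[1]), int(f[2])), float(f[3])))
    return out


def write_bedgraph(path: str | os.PathLike, probes: Iterable[ReplicationProbe]) -> None:
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t{p.score:.4f}\n")


# ---------------------------------------------------------------------------
# codon alignments (aligned FASTA, one record per taxon)
# ---------------------------------------------------------------------------


def read_codon_alignment_fasta(path: str | os.PathLike) -> CodonAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no records in {path}")
    return CodonAlignment(
        taxa=tuple(r.id for r in records),
        rows=tuple(str(r.seq).upper() for r in records),
    )


def write_codon_alignment_fasta(
    path: str | os.PathLike, aln: CodonAlignment, width: int = 60
) -> None:
    records = [
        SeqRecord(Seq(row), id=taxon, description="") for taxon, row in zip(aln.taxa, aln.rows)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_alignment_dir(directory: str | os.PathLike) -> dict[str, CodonAlignment]:
    """Per-gene alignments from ``<dir>/<gene_id>.fasta``."""
    out = {}
    for path in sorted(Path(directory).glob("*.fasta")):
        out[path.stem] = read_codon_alignment_fasta(path)
    return out


def write_alignment_dir(directory: str | os.PathLike, alignments: Mapping[str, CodonAlignment]) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for gene in sorted(alignments):
        write_codon_alignment_fasta(d / f"{gene}.fasta", alignments[gene])


# ---------------------------------------------------------------------------
# assignment tables
# ---------------------------------------------------------------------------


def write_assignments(path: str | os.PathLike, assignments) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tstatus\tcoverage\n")
        for a in assignments:
            fh.write(f"{a.locus_id}\t{a.status}\t{a.coverage:.4f}\n")
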
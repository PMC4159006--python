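"""Seeded synthetic-genome generator with planted ground truth.

The generator emulates the statistical structure of the underreplication
study on a scaled-down genome: a minority of the genome is designated as
underreplicated (UR) regions; genes planted inside those regions carry
conservation labels with different probabilities than genes outside;
conserved-element tracks are laid down with per-category densities that are
a configurable multiple higher inside the regions; replication-timing probes
give conserved genes earlier (higher) scores; and per-gene codon alignments
evolve on a star phylogeny with a group-specific nonsynonymous rate. Every
planted truth is recorded in a manifest so downstream recovery can be
checked against the single authoritative source.

The default configuration is a fixed 1:5-scale rendition of the study
conditions: ~12% of a 24-Mb three-chromosome genome inside 12 UR regions,
7% of 2,000 genes inside, label contrasts matching the published inside vs.
genome-wide fractions, element-density multipliers matching the published
intronic/intergenic enrichments, replication-score means 1.4 (conserved) vs
0.5 (nonconserved), and a 1.4-fold nonsynonymous rate contrast.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io as urio
from .divergence import (
    AA,
    BASES,
    CODON_INDEX,
    CODONS,
    IS_STOP,
    SITE_CLASS,
    CLASS_COUNTS,
    CodonAlignment,
    is_transition,
)
from .intervals import (
    GenomicInterval,
    RegionSet,
    complement,
    coverage_fraction,
    intersect_sets,
    partition_annotation,
    subtract_sets,
)
from .loci import Isoform, Locus
from .scores import ReplicationProbe

logger = logging.getLogger(__name__)

_SENSE = np.flatnonzero(~IS_STOP)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class CodonModelConfig:
    """Star-phylogeny codon substitution model.

    Branch lengths are expected substitutions per 4-fold site per branch, so
    the expected 4-fold pairwise distance of taxa (i, j) is b_i + b_j.
    ``omega_*`` is the nonsynonymous/synonymous rate ratio applied to genes
    planted inside vs. outside the UR regions (inside/outside = 1.4, the
    planted contrast)."""

    taxa: tuple[str, ...] = (
        "dmel", "dsim", "dyak", "dere", "dana", "dpse", "dper", "dwil",
    )
    branch_lengths: tuple[float, ...] = (0.03, 0.05, 0.08, 0.12, 0.20, 0.25, 0.28, 0.45)
    kappa: float = 2.0
    omega_inside: float = 0.14
    omega_outside: float = 0.10
    n_codons: int | None = None  # None: use each gene's protein length


@dataclass
class ElementTrackConfig:
    """One conserved-element track: lengths and per-category densities.

    ``densities`` maps an annotation category to (outside density per Mb,
    inside-region multiplier)."""

    length_range: tuple[int, int]
    densities: dict[str, tuple[float, float]]


@dataclass
class ReplicationConfig:
    probe_step: int = 1000
    probe_length: int = 800
    mean_conserved: float = 1.4
    mean_nonconserved: float = 0.5
    locus_sd: float = 1.5
    probe_noise: float = 0.3
    baseline_sd: float = 1.5


@dataclass
class NcRNAConfig:
    """Short/long noncoding RNA census conditions. ``inside_multiplier``
    thins placements falling inside UR regions (0 = complete depletion)."""

    counts: dict[str, int] = field(
        default_factory=lambda: {"miRNA": 26, "snoRNA": 24, "tRNA": 38, "lincRNA": 110}
    )
    inside_multiplier: dict[str, float] = field(
        default_factory=lambda: {"miRNA": 0.35, "snoRNA": 0.0, "tRNA": 0.55, "lincRNA": 1.0}
    )
    length_range: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"miRNA": (80, 120), "snoRNA": (70, 200), "tRNA": (71, 74)}
    )
    linc_mean_length_inside: float = 2200.0
    linc_mean_length_outside: float = 1700.0
    linc_min_length: int = 200


def _default_label_probs() -> dict[str, tuple[float, float]]:
    # flag -> (P inside UR, P outside): the published inside vs genome-wide
    # fractions for homology labels, 35% vs 13% testis-specific among genes
    # with known expression
    return {
        "human_homolog": (0.111, 0.43),
        "mosquito_homolog": (0.542, 0.772),
        "virilis_homolog": (0.93, 0.97),
        "expression_known": (0.90, 0.90),
        "testis_specific": (0.35, 0.13),
    }


def _default_elements() -> dict[str, ElementTrackConfig]:
    # outside densities per Mb and inside multipliers follow the published
    # per-category densities and intronic/intergenic enrichment ratios
    return {
        "uce": ElementTrackConfig(
            length_range=(100, 300),
            densities={"intronic": (11.9, 2.0), "intergenic": (24.1, 1.3)},
        ),
        "phastcons": ElementTrackConfig(
            length_range=(20, 200),
            densities={"intronic": (99.7, 1.9), "intergenic": (194.1, 1.2)},
        ),
        "hcne": ElementTrackConfig(
            length_range=(50, 200),
            densities={"intronic": (54.9, 2.2), "intergenic": (112.7, 1.4)},
        ),
    }


@dataclass
class SyntheticGenomeConfig:
    """Full generator parameterisation. The seed is mandatory; identical
    seed and config produce a byte-identical bundle."""

    seed: int
    chromosomes: tuple[tuple[str, int], ...] = (
        ("chrX", 8_000_000),
        ("chr2", 8_000_000),
        ("chr3", 8_000_000),
    )
    n_regions: int = 12
    region_length_range: tuple[int, int] = (150_000, 350_000)
    n_loci: int = 2000
    frac_loci_in_regions: float = 0.07
    # long-tailed protein lengths (aa): lognormal, median ~330, mean ~450
    protein_log_mean: float = 5.8
    protein_log_sd: float = 0.8
    min_protein: int = 50
    # span = CDS x intron-expansion factor (long-tailed so very long genes exist)
    intron_factor_log_mean: float = 0.8
    intron_factor_log_sd: float = 1.1
    multi_isoform_fraction: float = 0.0
    label_probs: dict[str, tuple[float, float]] = field(default_factory=_default_label_probs)
    est_support_given_virilis: float = 0.90
    est_support_no_virilis: float = 0.83
    elements: dict[str, ElementTrackConfig] = field(default_factory=_default_elements)
    phastcons_score_range: tuple[int, int] = (601, 1000)
    phastcons_decoy_fraction: float = 1.0  # sub-threshold decoys per real element
    phastcons_decoy_score_range: tuple[int, int] = (100, 600)
    hcne_short_decoy_fraction: float = 0.2
    hcne_exonic_decoy_fraction: float = 0.1
    hcne_noise_fraction: float = 0.5
    replication: ReplicationConfig = field(default_factory=ReplicationConfig)
    ncrna: NcRNAConfig = field(default_factory=NcRNAConfig)
    codon: CodonModelConfig = field(default_factory=CodonModelConfig)
    #: genes within this distance of a region get codon alignments
    #: ("all" behaviour: set to a huge value)
    alignment_flank: int = 300_000

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed is mandatory and must be an integer")
        for flag, (p_in, p_out) in self.label_probs.items():
            if not (0 <= p_in <= 1 and 0 <= p_out <= 1):
                raise ValueError(f"label probability out of [0,1] for {flag}")
        for name, track in self.elements.items():
            for cat, (dens, mult) in track.densities.items():
                if dens < 0 or mult < 0:
                    raise ValueError(f"negative density for {name}/{cat}")
        if not (0 <= self.frac_loci_in_regions <= 1):
            raise ValueError("frac_loci_in_regions out of [0,1]")


# ---------------------------------------------------------------------------
# bundle container
# ---------------------------------------------------------------------------


@dataclass
class SyntheticBundle:
    config: SyntheticGenomeConfig
    chromosomes: list[GenomicInterval]
    regions: RegionSet
    loci: list[Locus]
    ncrna: list[Locus]
    uce: list[GenomicInterval]
    phastcons: list[tuple[GenomicInterval, float]]
    hcne_tracks: list[list[GenomicInterval]]
    probes: list[ReplicationProbe]
    alignments: dict[str, CodonAlignment]
    manifest: dict


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _quota_split(rng: np.random.Generator, weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` over ``weights``."""
    if weights.sum() <= 0:
        raise ValueError("cannot apportion over zero weight")
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def _make_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    start: int,
    max_span: int,
    cfg: SyntheticGenomeConfig,
) -> Locus | None:
    """One protein-coding gene model starting at ``start``, span <= max_span."""
    aa = max(cfg.min_protein, int(rng.lognormal(cfg.protein_log_mean, cfg.protein_log_sd)))
    utr5 = min(int(rng.integers(50, 300)), max(20, max_span // 10))
    utr3 = min(int(rng.integers(50, 300)), max(20, max_span // 10))
    aa_cap = (max_span - utr5 - utr3 - 60) // 3 - 2
    if aa_cap < 20:
        return None
    aa = min(aa, aa_cap)
    cds_len = 3 * (aa + 1)  # stop codon inside the CDS range
    factor = float(rng.lognormal(cfg.intron_factor_log_mean, cfg.intron_factor_log_sd))
    exonic = utr5 + cds_len + utr3
    span_len = min(max_span, max(exonic, int(cds_len * max(1.0, factor)) + utr5 + utr3))
    intron_total = span_len - exonic
    max_exons = max(1, min(6, cds_len // 90))
    n_exons = int(rng.integers(1, max_exons + 1))
    if intron_total < 40 * (n_exons - 1):
        n_exons = max(1, intron_total // 40 + 1 if intron_total >= 40 else 1)
        n_exons = min(n_exons, max_exons)
    # split the CDS into n_exons chunks of >=30 bp
    if n_exons > 1:
        cuts = np.sort(rng.choice(np.arange(30, cds_len - 29), size=n_exons - 1, replace=False))
        chunks = np.diff(np.concatenate([[0], cuts, [cds_len]])).tolist()
        if min(chunks) < 10:  # re-split evenly on a bad draw
            chunks = [cds_len // n_exons] * n_exons
            chunks[-1] += cds_len - sum(chunks)
        w = rng.random(n_exons - 1)
        introns = np.maximum(40, (w / w.sum() * (intron_total - 40 * (n_exons - 1)) + 40)).astype(int)
        introns[-1] += intron_total - int(introns.sum())
        if introns[-1] < 40:
            deficit = 40 - int(introns[-1])
            introns[-1] = 40
            introns[0] = max(40, int(introns[0]) - deficit)
        introns = introns.tolist()
    else:
        chunks, introns = [cds_len], []

    strand = "+" if rng.random() < 0.5 else "-"
    exons: list[GenomicInterval] = []
    cds_blocks: list[GenomicInterval] = []
    ptr = start
    for k, chunk in enumerate(chunks):
        ex_start = ptr
        ex_len = chunk + (utr5 if k == 0 else 0) + (utr3 if k == n_exons - 1 else 0)
        exons.append(GenomicInterval(chrom, ex_start, ex_start + ex_len, strand))
        cds_start = ex_start + (utr5 if k == 0 else 0)
        cds_blocks.append(GenomicInterval(chrom, cds_start, cds_start + chunk, strand))
        ptr = ex_start + ex_len + (introns[k] if k < len(introns) else 0)
    span = GenomicInterval(chrom, start, exons[-1].end, strand)
    isoforms = [Isoform(name="RA", span=span, exons=tuple(exons), cds=tuple(cds_blocks))]
    if rng.random() < cfg.multi_isoform_fraction and n_exons > 1:
        # a second, shorter isoform exercising the span/alphabetical rules
        sub_exons = tuple(exons[:-1])
        sub_cds = tuple(c for c in cds_blocks[:-1])
        sub_span = GenomicInterval(chrom, span.start, sub_exons[-1].end, strand)
        isoforms.append(Isoform(name="RB", span=sub_span, exons=sub_exons, cds=sub_cds))
    return Locus(
        id=gene_id,
        chrom=chrom,
        isoforms=tuple(isoforms),
        protein_length=aa,
        labels=frozenset(),
    )


def _fill_segment_with_genes(
    rng: np.random.Generator,
    segment: GenomicInterval,
    quota: int,
    next_id,
    cfg: SyntheticGenomeConfig,
) -> list[Locus]:
    """Place exactly ``quota`` non-overlapping genes inside ``segment``."""
    out: list[Locus] = []
    min_footprint = 900  # smallest gene + gap that can still be placed
    ptr = segment.start + int(rng.integers(100, 1000))
    for k in range(quota):
        remaining = quota - k
        avail = segment.end - ptr
        if avail < remaining * min_footprint:
            raise ValueError(
                f"infeasible config: cannot fit {quota} genes in {segment} "
                f"({len(out)} placed)"
            )
        # cap spans so the remaining quota always fits
        max_span = min(int(avail / remaining * 1.6), avail - (remaining - 1) * min_footprint - 100)
        gene = _make_gene(rng, next_id(), segment.chrom, ptr, max_span, cfg)
        if gene is None:
            raise ValueError(f"infeasible config: gene does not fit in {segment}")
        out.append(gene)
        slack = segment.end - gene.span.end - (remaining - 1) * min_footprint
        gap = int(rng.integers(100, 1500))
        ptr = gene.span.end + max(50, min(gap, slack)) if remaining > 1 else gene.span.end + gap
    return out


def _place_elements(
    rng: np.random.Generator,
    space: RegionSet,
    count: int,
    length_range: tuple[int, int],
    avoid: list[GenomicInterval] | None = None,
) -> list[GenomicInterval]:
    """Drop ``count`` elements uniformly into a region set, each fully inside
    one segment (so its midpoint category is unambiguous).

    With ``avoid``, candidates overlapping or book-ending any interval in the
    list are redrawn and successful placements are appended to it — used when
    elements must stay distinct under interval merging.
    """
    segments = list(space)
    if not segments:
        if count:
            logger.warning("no space available for %d elements", count)
        return []
    seg_lens = np.array([s.length for s in segments], dtype=float)
    placed: list[GenomicInterval] = []
    avoid_set = RegionSet(avoid) if avoid is not None else None
    for _ in range(count):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        w = np.maximum(seg_lens - L + 1, 0.0)
        if w.sum() <= 0:
            L = int(seg_lens.max())
            w = np.maximum(seg_lens - L + 1, 0.0)
            if w.sum() <= 0:
                continue
        for _attempt in range(30):
            seg = segments[int(rng.choice(len(segments), p=w / w.sum()))]
            start = seg.start + int(rng.integers(0, seg.length - L + 1))
            cand = GenomicInterval(seg.chrom, start, start + L)
            if avoid is None:
                break
            # extend by 1 bp: book-ended intervals would merge downstream
            probe = GenomicInterval(cand.chrom, max(0, cand.start - 1), cand.end + 1)
            if not avoid_set.overlaps(probe):
                avoid.append(cand)
                avoid_set = RegionSet(avoid)
                break
        else:
            logger.warning("could not place an element without adjacency; skipped")
            continue
        placed.append(cand)
    return placed


def _poisson_counts(
    rng: np.random.Generator, density_per_mb: float, length_bp: int
) -> int:
    return int(rng.poisson(density_per_mb * length_bp / 1e6))


# ---------------------------------------------------------------------------
# codon simulation
# ---------------------------------------------------------------------------

_CHANNEL_CACHE: dict[tuple[float, float], tuple] = {}


def _channel_tables(kappa: float, omega: float):
    """Per-codon substitution channels: targets, weights, syn flags, positions."""
    key = (kappa, omega)
    if key in _CHANNEL_CACHE:
        return _CHANNEL_CACHE[key]
    targets: list[np.ndarray] = []
    cumw: list[np.ndarray] = []
    syn: list[np.ndarray] = []
    pos: list[np.ndarray] = []
    total = np.zeros(64)
    for i, c in enumerate(CODONS):
        if IS_STOP[i]:
            targets.append(np.empty(0, dtype=np.int64))
            cumw.append(np.empty(0))
            syn.append(np.empty(0, dtype=bool))
            pos.append(np.empty(0, dtype=np.int64))
            continue
        t_, w_, s_, p_ = [], [], [], []
        for p in range(3):
            for b in BASES:
                if b == c[p]:
                    continue
                j = CODON_INDEX[c[:p] + b + c[p + 1 :]]
                if IS_STOP[j]:
                    continue  # proposals creating stop codons are rejected
                is_syn = AA[j] == AA[i]
                w = (kappa if is_transition(c[p], b) else 1.0) * (1.0 if is_syn else omega)
                t_.append(j)
                w_.append(w)
                s_.append(is_syn)
                p_.append(p)
        targets.append(np.asarray(t_, dtype=np.int64))
        warr = np.asarray(w_)
        cumw.append(np.cumsum(warr))
        syn.append(np.asarray(s_, dtype=bool))
        pos.append(np.asarray(p_, dtype=np.int64))
        total[i] = warr.sum()
    out = (targets, cumw, syn, pos, total)
    _CHANNEL_CACHE[key] = out
    return out


@dataclass
class CodonSimStats:
    """Realized-substitution ground truth for one simulated alignment."""

    ancestor_class_counts: tuple[float, float, float]  # L0, L2, L4 of the ancestor
    syn_events: list[int]  # per taxon
    nonsyn_events: list[int]
    syn_events_4fold: list[int]  # synonymous events at 4-fold classified sites
    ancestor_codon_counts: np.ndarray | None = None  # 64-vector of codon usage


def effective_site_counts(
    codon_counts: np.ndarray, kappa: float, omega: float
) -> tuple[float, float]:
    """Effective synonymous/nonsynonymous site counts of a codon composition.

    Sites are weighted by the substitution process's actual mutational
    opportunity: a site contributes (synonymous channel weight)/(kappa+2)
    synonymous sites, and the nonsynonymous weight (with the omega factor
    divided back out) analogously, so realized event counts divided by these
    totals estimate per-site rates exactly in expectation.
    """
    targets, cumw, syn, _pos, _total = _channel_tables(kappa, omega)
    syn_sites = nonsyn_sites = 0.0
    for c in range(64):
        n = float(codon_counts[c])
        if n == 0 or len(targets[c]) == 0:
            continue
        w = np.diff(np.concatenate([[0.0], cumw[c]]))
        syn_sites += n * w[syn[c]].sum() / (kappa + 2.0)
        nonsyn_sites += n * (w[~syn[c]].sum() / omega) / (kappa + 2.0)
    return syn_sites, nonsyn_sites


def simulate_codon_alignment(
    n_codons: int,
    model: CodonModelConfig,
    omega: float,
    rng: np.random.Generator,
) -> tuple[CodonAlignment, CodonSimStats]:
    """Evolve a stop-free ancestral codon string along a star tree.

    Substitution proposals follow a nucleotide process with transition bias
    kappa; nonsynonymous changes are slowed by ``omega`` and proposals
    creating stop codons are rejected. The per-branch rate is normalised so
    a 4-fold degenerate site accumulates ``branch_length`` substitutions in
    expectation. Realized substitution counts per branch are returned as
    ground truth.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    targets, cumw, syn, pos, total_w = _channel_tables(model.kappa, omega)
    anc = _SENSE[rng.integers(0, len(_SENSE), size=n_codons)]
    cc = CLASS_COUNTS[anc].sum(axis=0)
    rows: list[str] = []
    stats = CodonSimStats(
        ancestor_class_counts=(float(cc[0]), float(cc[1]), float(cc[2])),
        syn_events=[], nonsyn_events=[], syn_events_4fold=[],
        ancestor_codon_counts=np.bincount(anc, minlength=64),
    )
    mu_unit = 1.0 / (model.kappa + 2.0)  # 4-fold site total rate = kappa+2 channels
    for b in model.branch_lengths:
        seq = anc.copy()
        n_syn = n_nonsyn = n_syn4 = 0
        if b > 0:
            mu = b * mu_unit
            rate = mu * total_w[seq]
            waits = rng.exponential(1.0, size=n_codons) / rate
            for site in np.flatnonzero(waits < 1.0).tolist():
                t = waits[site]
                cur = int(seq[site])
                while t < 1.0:
                    r = rng.random() * total_w[cur]
                    k = int(np.searchsorted(cumw[cur], r))
                    k = min(k, len(targets[cur]) - 1)
                    p = int(pos[cur][k])
                    if syn[cur][k]:
                        n_syn += 1
                        if SITE_CLASS[cur, p] == 4:
                            n_syn4 += 1
                    else:
                        n_nonsyn += 1
                    cur = int(targets[cur][k])
                    t += rng.exponential(1.0) / (mu * total_w[cur])
                seq[site] = cur
        rows.append("".join(CODONS[k] for k in seq.tolist()))
        stats.syn_events.append(n_syn)
        stats.nonsyn_events.append(n_nonsyn)
        stats.syn_events_4fold.append(n_syn4)
    aln = CodonAlignment(taxa=tuple(model.taxa), rows=tuple(rows))
    return aln, stats


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------


def simulate_genome(config: SyntheticGenomeConfig) -> SyntheticBundle:
    """Generate the full input bundle plus the ground-truth manifest."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chromosomes = [GenomicInterval(name, 0, length) for name, length in config.chromosomes]
    manifest: dict = {"config": _config_dict(config)}

    # --- UR regions: one per equal slot, margins keep them well separated
    chrom_lens = np.array([c.length for c in chromosomes], dtype=float)
    region_quota = _quota_split(rng, chrom_lens, config.n_regions)
    region_ivs: list[GenomicInterval] = []
    lo, hi = config.region_length_range
    for chrom, nq in zip(chromosomes, region_quota):
        if nq == 0:
            continue
        slot = chrom.length // int(nq)
        if slot < hi + 100_000:
            raise ValueError("infeasible config: regions do not fit their chromosome")
        for k in range(int(nq)):
            rlen = int(rng.integers(lo, hi + 1))
            margin = 50_000
            start = chrom.start + k * slot + margin + int(
                rng.integers(0, slot - rlen - 2 * margin)
            )
            region_ivs.append(GenomicInterval(chrom.chrom, start, start + rlen))
    regions = RegionSet(region_ivs, name="UR")

    # --- protein-coding loci
    n_inside = round(config.n_loci * config.frac_loci_in_regions)
    n_outside = config.n_loci - n_inside
    counter = iter(range(10 ** 6))

    def next_id() -> str:
        return f"g{next(counter):05d}"

    inside_loci: list[Locus] = []
    inside_quota = _quota_split(
        rng, np.array([iv.length for iv in region_ivs], dtype=float), n_inside
    )
    for iv, nq in zip(region_ivs, inside_quota):
        inside_loci.extend(_fill_segment_with_genes(rng, iv, int(nq), next_id, config))
    outside_space = complement(regions, chromosomes)
    # keep clear of region borders so "outside" genes never touch a region
    buffered = RegionSet(
        [GenomicInterval(iv.chrom, max(0, iv.start - 2000), iv.end + 2000) for iv in region_ivs]
    )
    outside_segments = [
        iv for iv in complement(buffered, chromosomes) if iv.length > 20_000
    ]
    outside_quota = _quota_split(
        rng, np.array([iv.length for iv in outside_segments], dtype=float), n_outside
    )
    outside_loci: list[Locus] = []
    for iv, nq in zip(outside_segments, outside_quota):
        outside_loci.extend(_fill_segment_with_genes(rng, iv, int(nq), next_id, config))
    loci = sorted(inside_loci + outside_loci, key=lambda l: (l.chrom, l.span.start))
    inside_ids = {l.id for l in inside_loci}
    manifest["loci_inside"] = sorted(inside_ids)
    manifest["n_loci"] = len(loci)

    # --- labels
    label_counts: dict[str, dict[str, int]] = {}
    for locus in loci:
        status = "inside" if locus.id in inside_ids else "outside"
        col = 0 if status == "inside" else 1
        flags = set()
        for flag in ("human_homolog", "mosquito_homolog", "virilis_homolog", "expression_known"):
            if rng.random() < config.label_probs[flag][col]:
                flags.add(flag)
        if "expression_known" in flags and rng.random() < config.label_probs["testis_specific"][col]:
            flags.add("testis_specific")
        p_est = (
            config.est_support_given_virilis
            if "virilis_homolog" in flags
            else config.est_support_no_virilis
        )
        if rng.random() < p_est:
            flags.add("est_support")
        locus.labels = frozenset(flags)
        for flag in flags:
            label_counts.setdefault(flag, {"inside": 0, "outside": 0})[status] += 1
    manifest["label_counts"] = label_counts
    manifest["n_inside"] = len(inside_ids)

    # --- annotation partition and element tracks
    partition = partition_annotation(loci, chromosomes)
    spaces = {}
    for cat in ("exonic", "intronic", "intergenic"):
        cat_set = partition.get(cat)
        spaces[(cat, "inside")] = intersect_sets(cat_set, regions)
        spaces[(cat, "outside")] = subtract_sets(cat_set, regions)

    element_counts: dict[str, dict[str, dict[str, int]]] = {}
    uce: list[GenomicInterval] = []
    phastcons: list[tuple[GenomicInterval, float]] = []
    hcne_cores: list[GenomicInterval] = []
    hcne_avoid: list[GenomicInterval] = []
    for track_name, track in config.elements.items():
        element_counts[track_name] = {}
        for cat, (dens_out, mult_in) in track.densities.items():
            placed_by_status = {}
            for status, dens in (("inside", dens_out * mult_in), ("outside", dens_out)):
                space = spaces[(cat, status)]
                n = _poisson_counts(rng, dens, space.total_length())
                placed = _place_elements(
                    rng, space, n, track.length_range,
                    avoid=hcne_avoid if track_name == "hcne" else None,
                )
                placed_by_status[status] = placed
            element_counts[track_name][cat] = {
                s: len(v) for s, v in placed_by_status.items()
            }
            both = placed_by_status["inside"] + placed_by_status["outside"]
            if track_name == "uce":
                uce.extend(both)
            elif track_name == "phastcons":
                for iv in both:
                    score = float(rng.integers(*config.phastcons_score_range))
                    phastcons.append((iv, score))
            elif track_name == "hcne":
                hcne_cores.extend(both)
    # sub-threshold phastcons decoys (filtered out by the score cut downstream)
    n_decoys = int(len(phastcons) * config.phastcons_decoy_fraction)
    decoy_space = spaces[("intergenic", "outside")]
    for iv in _place_elements(
        rng, decoy_space, n_decoys, config.elements["phastcons"].length_range
    ):
        phastcons.append((iv, float(rng.integers(*config.phastcons_decoy_score_range))))
    phastcons.sort(key=lambda t: (t[0].chrom, t[0].start))
    uce.sort(key=lambda iv: (iv.chrom, iv.start))
    manifest["element_counts"] = element_counts

    # --- HCNE tracks: cores present in all four tracks; short and exonic
    #     decoys also present in all four (removed by the filters); per-track
    #     noise removed by the AND intersection
    n_cores = len(hcne_cores)
    short_decoys = _place_elements(
        rng,
        spaces[("intergenic", "outside")],
        int(n_cores * config.hcne_short_decoy_fraction),
        (20, 49),
        avoid=hcne_avoid,
    )
    exonic_space = RegionSet(
        list(spaces[("exonic", "inside")]) + list(spaces[("exonic", "outside")])
    )
    exonic_decoys = _place_elements(
        rng,
        exonic_space,
        int(n_cores * config.hcne_exonic_decoy_fraction),
        (50, 200),
        avoid=hcne_avoid,
    )
    shared = hcne_cores + short_decoys + exonic_decoys
    # noise must stay clear of shared elements and of noise in other tracks,
    # so the AND of the four tracks recovers exactly the shared elements
    claimed = RegionSet(
        [GenomicInterval(iv.chrom, max(0, iv.start - 100), iv.end + 100) for iv in shared]
    )
    noise_claimed: list[GenomicInterval] = []
    chrom_by_name = {c.chrom: c for c in chromosomes}
    hcne_tracks: list[list[GenomicInterval]] = []
    n_noise = int(n_cores * config.hcne_noise_fraction)
    for t in range(4):
        if t == 0:
            track_ivs = list(shared)
        else:
            track_ivs = [
                GenomicInterval(
                    iv.chrom,
                    max(0, iv.start - int(rng.integers(0, 41))),
                    min(chrom_by_name[iv.chrom].end, iv.end + int(rng.integers(0, 41))),
                )
                for iv in shared
            ]
        noise_set = RegionSet(noise_claimed)
        for _ in range(n_noise):
            for _attempt in range(20):
                chrom = chromosomes[int(rng.integers(0, len(chromosomes)))]
                L = int(rng.integers(50, 201))
                start = int(rng.integers(0, chrom.length - L))
                cand = GenomicInterval(chrom.chrom, start, start + L)
                if not claimed.overlaps(cand) and not noise_set.overlaps(cand):
                    track_ivs.append(cand)
                    noise_claimed.append(cand)
                    noise_set = RegionSet(noise_claimed)
                    break
        track_ivs.sort(key=lambda iv: (iv.chrom, iv.start))
        hcne_tracks.append(track_ivs)
    manifest["hcne"] = {
        "n_cores_valid": n_cores,
        "n_short_decoys": len(short_decoys),
        "n_exonic_decoys": len(exonic_decoys),
        "core_count_inside": sum(
            1 for iv in hcne_cores if regions.contains_point(iv.chrom, iv.midpoint)
        ),
    }

    # --- noncoding RNAs
    ncrna: list[Locus] = []
    nc_counter = iter(range(10 ** 6))
    nc_counts: dict[str, dict[str, int]] = {}
    total_len = int(chrom_lens.sum())
    for cls in ("miRNA", "snoRNA", "tRNA"):
        n = config.ncrna.counts.get(cls, 0)
        mult = config.ncrna.inside_multiplier.get(cls, 1.0)
        lo_len, hi_len = config.ncrna.length_range[cls]
        placed = 0
        nc_counts[cls] = {"inside": 0, "outside": 0}
        while placed < n:
            chrom = chromosomes[int(rng.choice(len(chromosomes), p=chrom_lens / chrom_lens.sum()))]
            L = int(rng.integers(lo_len, hi_len + 1))
            start = int(rng.integers(0, chrom.length - L))
            iv = GenomicInterval(chrom.chrom, start, start + L)
            inside = regions.contains_point(iv.chrom, iv.midpoint)
            if inside and rng.random() >= mult:
                continue  # thinned inside the regions (planted depletion)
            span = iv
            ncrna.append(
                Locus(
                    id=f"nc{next(nc_counter):05d}",
                    chrom=span.chrom,
                    isoforms=(Isoform(name="RA", span=span, exons=(span,)),),
                    ncrna_class=cls,
                )
            )
            nc_counts[cls]["inside" if inside else "outside"] += 1
            placed += 1
    # lincRNAs live in intergenic space; inside/outside split is
    # length-proportional, lengths longer inside
    n_linc = config.ncrna.counts.get("lincRNA", 0)
    ig_in = spaces[("intergenic", "inside")]
    ig_out = spaces[("intergenic", "outside")]
    lens = np.array([ig_in.total_length(), ig_out.total_length()], dtype=float)
    linc_quota = _quota_split(rng, lens, n_linc)
    nc_counts["lincRNA"] = {"inside": int(linc_quota[0]), "outside": int(linc_quota[1])}
    for status, space, nq, mean_len in (
        ("inside", ig_in, int(linc_quota[0]), config.ncrna.linc_mean_length_inside),
        ("outside", ig_out, int(linc_quota[1]), config.ncrna.linc_mean_length_outside),
    ):
        segments = [s for s in space if s.length > config.ncrna.linc_min_length * 2]
        seg_lens = np.array([s.length for s in segments], dtype=float)
        for _ in range(nq):
            L = max(config.ncrna.linc_min_length, int(rng.exponential(mean_len)))
            w = np.maximum(seg_lens - L + 1, 0.0)
            if w.sum() <= 0:
                L = int(seg_lens.max() // 2)
                w = np.maximum(seg_lens - L + 1, 0.0)
            seg = segments[int(rng.choice(len(segments), p=w / w.sum()))]
            start = seg.start + int(rng.integers(0, seg.length - L + 1))
            span = GenomicInterval(seg.chrom, start, start + L)
            ncrna.append(
                Locus(
                    id=f"nc{next(nc_counter):05d}",
                    chrom=span.chrom,
                    isoforms=(Isoform(name="RA", span=span, exons=(span,)),),
                    ncrna_class="lincRNA",
                )
            )
    manifest["ncrna_counts"] = nc_counts
    manifest["linc_mean_length"] = {
        "inside": config.ncrna.linc_mean_length_inside,
        "outside": config.ncrna.linc_mean_length_outside,
    }

    # --- replication probes
    rep = config.replication
    latent: dict[str, float] = {}
    for locus in loci:
        mean = rep.mean_conserved if locus.has("human_homolog") else rep.mean_nonconserved
        latent[locus.id] = float(rng.normal(mean, rep.locus_sd))
    probes: list[ReplicationProbe] = []
    for chrom in chromosomes:
        spans = [(l.span.start, l.span.end, l.id) for l in loci if l.chrom == chrom.chrom]
        spans.sort()
        starts = np.array([s[0] for s in spans])
        ends = np.array([s[1] for s in spans])
        for pstart in range(0, chrom.length - rep.probe_length, rep.probe_step):
            pend = pstart + rep.probe_length
            # a probe carries the signal of the locus it overlaps most
            i = int(np.searchsorted(ends, pstart, side="right"))
            j = int(np.searchsorted(starts, pend, side="left"))
            best_id, best_ov = None, 0
            for k in range(i, j):
                ov = min(ends[k], pend) - max(starts[k], pstart)
                if ov > best_ov:
                    best_id, best_ov = spans[k][2], ov
            if best_id is not None and best_ov >= 5:
                score = latent[best_id] + float(rng.normal(0, rep.probe_noise))
            else:
                score = float(rng.normal(0, rep.baseline_sd))
            probes.append(
                ReplicationProbe(
                    GenomicInterval(chrom.chrom, pstart, pstart + rep.probe_length), score
                )
            )
    cons = [latent[l.id] for l in loci if l.has("human_homolog")]
    noncons = [latent[l.id] for l in loci if not l.has("human_homolog")]
    manifest["replication"] = {
        "planted_mean_conserved": rep.mean_conserved,
        "planted_mean_nonconserved": rep.mean_nonconserved,
        "realized_mean_conserved": float(np.mean(cons)) if cons else None,
        "realized_mean_nonconserved": float(np.mean(noncons)) if noncons else None,
    }

    # --- codon alignments for genes near the regions
    flank = RegionSet(
        [
            GenomicInterval(
                iv.chrom,
                max(0, iv.start - config.alignment_flank),
                min(chrom_by_name[iv.chrom].end, iv.end + config.alignment_flank),
            )
            for iv in region_ivs
        ]
    )
    alignments: dict[str, CodonAlignment] = {}
    codon_truth: dict[str, dict] = {}
    for locus in loci:
        if not flank.overlaps(locus.span):
            continue
        status = "inside" if locus.id in inside_ids else "outside"
        omega = config.codon.omega_inside if status == "inside" else config.codon.omega_outside
        n_codons = config.codon.n_codons or locus.protein_length
        child = np.random.default_rng(rng.integers(0, 2 ** 31))
        aln, st = simulate_codon_alignment(n_codons, config.codon, omega, child)
        alignments[locus.id] = aln
        codon_truth[locus.id] = {
            "status": status,
            "omega": omega,
            "n_codons": n_codons,
            "ancestor_class_counts": list(st.ancestor_class_counts),
            "syn_events": st.syn_events,
            "nonsyn_events": st.nonsyn_events,
            "syn_events_4fold": st.syn_events_4fold,
        }
    manifest["codon"] = {
        "taxa": list(config.codon.taxa),
        "branch_lengths": list(config.codon.branch_lengths),
        "kappa": config.codon.kappa,
        "omega_inside": config.codon.omega_inside,
        "omega_outside": config.codon.omega_outside,
        "per_gene": codon_truth,
    }

    return SyntheticBundle(
        config=config,
        chromosomes=chromosomes,
        regions=regions,
        loci=loci,
        ncrna=ncrna,
        uce=uce,
        phastcons=phastcons,
        hcne_tracks=hcne_tracks,
        probes=probes,
        alignments=alignments,
        manifest=manifest,
    )


def _config_dict(config: SyntheticGenomeConfig) -> dict:
    d = dataclasses.asdict(config)

    def _clean(x):
        if isinstance(x, dict):
            return {str(k): _clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [_clean(v) for v in x]
        return x

    return _clean(d)


# ---------------------------------------------------------------------------
# bundle I/O
# ---------------------------------------------------------------------------


def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    """Write the bundle as plain-text files plus the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "chromosomes.tsv", "w") as fh:
        fh.write("chrom\tlength\n")
        for c in bundle.chromosomes:
            fh.write(f"{c.chrom}\t{c.length}\n")
    urio.write_bed(out / "regions.bed", bundle.regions)
    urio.write_bed12_loci(out / "genes.bed", bundle.loci)
    urio.write_bed12_loci(out / "ncrna.bed", bundle.ncrna)
    urio.write_label_table(out / "labels.tsv", list(bundle.loci) + list(bundle.ncrna))
    urio.write_bed(out / "uce.bed", bundle.uce)
    urio.write_scored_bed(out / "phastcons.bed", bundle.phastcons)
    for k, track in enumerate(bundle.hcne_tracks):
        urio.write_bed(out / f"hcne_track_{k}.bed", track)
    urio.write_bedgraph(out / "probes.bedgraph", bundle.probes)
    urio.write_alignment_dir(out / "alignments", bundle.alignments)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=1, sort_keys=True)
    # a small human-readable summary of the planted truth
    with open(out / "manifest_summary.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"n_loci\t{bundle.manifest['n_loci']}\n")
        fh.write(f"n_loci_inside\t{bundle.manifest['n_inside']}\n")
        fh.write(f"n_regions\t{len(bundle.regions)}\n")
        fh.write(f"hcne_cores_valid\t{bundle.manifest['hcne']['n_cores_valid']}\n")


def load_bundle(directory) -> SyntheticBundle:
    """Load a written bundle back from disk (manifest included)."""
    d = Path(directory)
    chromosomes = []
    with open(d / "chromosomes.tsv") as fh:
        fh.readline()
        for line in fh:
            name, length = line.split("\t")
            chromosomes.append(GenomicInterval(name, 0, int(length)))
    regions = RegionSet(urio.read_bed(d / "regions.bed"), name="UR")
    loci = urio.read_bed12_loci(d / "genes.bed")
    ncrna = urio.read_bed12_loci(d / "ncrna.bed")
    labels = urio.read_label_table(d / "labels.tsv")
    urio.apply_labels(loci, labels)
    urio.apply_labels(ncrna, labels)
    uce = urio.read_bed(d / "uce.bed")
    phastcons = urio.read_scored_bed(d / "phastcons.bed")
    hcne_tracks = [
        urio.read_bed(d / f"hcne_track_{k}.bed") for k in range(4)
    ]
    probes = urio.read_bedgraph(d / "probes.bedgraph")
    alignments = urio.read_alignment_dir(d / "alignments")
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg_raw = manifest.get("config", {})
    config = SyntheticGenomeConfig(seed=cfg_raw.get("seed", 0))
    return SyntheticBundle(
        config=config,
        chromosomes=chromosomes,
        regions=regions,
        loci=loci,
        ncrna=ncrna,
        uce=uce,
        phastcons=phastcons,
        hcne_tracks=hcne_tracks,
        probes=probes,
        alignments=alignments,
        manifest=manifest,
    )
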
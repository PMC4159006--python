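"""Assignment of loci to underreplicated (UR) regions, matched adjacent-gene
controls, and construction of the filtered conserved-element (HCNE) set.

A locus belongs to the UR set when at least half of its genomic length —
measured from the left-most start to the right-most end over all isoforms —
is covered by UR regions, summed over all regions (a locus straddling two
regions counts its combined coverage). For every UR region an equally sized
control set of flanking genes is chosen, half upstream and half downstream,
excluding any gene that touches a UR region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .intervals import GenomicInterval, RegionSet, coverage_fraction, intersect_sets
from .loci import Locus

logger = logging.getLogger(__name__)

OUTSIDE = "outside"


@dataclass(frozen=True)
class Assignment:
    """Outcome of assigning one locus against the UR region set.

    ``status`` is the name of the best-overlapping region (coverage at or
    above the threshold), ``"adjacent:<region>"`` for selected controls, or
    ``"outside"``. ``coverage`` is the audited covered fraction of the locus
    span against the merged region set.
    """

    locus_id: str
    status: str
    coverage: float

    @property
    def in_region(self) -> bool:
        return self.status != OUTSIDE and not self.status.startswith("adjacent:")


def region_name(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def assign_loci(
    loci: Sequence[Locus], regions: RegionSet, threshold: float = 0.5
) -> list[Assignment]:
    """Assign each locus to the region set iff its span coverage >= threshold.

    The rule is "at least": a span exactly half covered is assigned at the
    default threshold. The named region is the single region interval with
    the largest overlap (left-most on ties).
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    out: list[Assignment] = []
    for locus in loci:
        span = locus.span
        cov = coverage_fraction(span, regions)
        if cov >= threshold:
            best, best_ov = None, -1
            starts, ends = regions.arrays(span.chrom)
            for s, e in zip(starts.tolist(), ends.tolist()):
                ov = max(0, min(e, span.end) - max(s, span.start))
                if ov > best_ov:
                    best, best_ov = GenomicInterval(span.chrom, s, e), ov
            assert best is not None
            out.append(Assignment(locus.id, region_name(best), cov))
        else:
            out.append(Assignment(locus.id, OUTSIDE, cov))
    return out


def select_adjacent_controls(
    region: GenomicInterval,
    n: int,
    loci: Sequence[Locus],
    regions: RegionSet,
    exclude_ids: Iterable[str] = (),
    strict: bool = True,
) -> list[Locus]:
    """Pick the ``n`` nearest eligible flanking genes for one UR region.

    ceil(n/2) genes are taken upstream (lower coordinates, nearest first by
    span end) and floor(n/2) downstream (nearest first by span start). A gene
    is eligible when it overlaps no UR region by even a single base and is
    not in ``exclude_ids`` (controls already claimed by another region).
    When one side runs out, the deficit is taken from the other side.

    Raises
    ------
    ValueError
        If fewer than ``n`` eligible genes exist on both sides combined and
        ``strict`` is true; with ``strict=False`` the short list is returned
        and a warning logged (mirrors a genome edge where flanks exhaust).
    """
    excluded = set(exclude_ids)
    upstream: list[tuple[int, str, Locus]] = []
    downstream: list[tuple[int, str, Locus]] = []
    for locus in loci:
        if locus.id in excluded or locus.chrom != region.chrom:
            continue
        span = locus.span
        if regions.overlaps(span):
            continue
        if span.end <= region.start:
            upstream.append((region.start - span.end, locus.id, locus))
        elif span.start >= region.end:
            downstream.append((span.start - region.end, locus.id, locus))
    upstream.sort(key=lambda t: (t[0], t[1]))
    downstream.sort(key=lambda t: (t[0], t[1]))

    n_up = math.ceil(n / 2)
    n_down = n // 2
    take_up = min(n_up, len(upstream))
    take_down = min(n_down, len(downstream))
    # redistribute any deficit to the other flank
    take_down = min(n - take_up, len(downstream))
    take_up = min(n - take_down, len(upstream))
    picked = [t[2] for t in upstream[:take_up]] + [t[2] for t in downstream[:take_down]]
    if len(picked) < n:
        msg = (
            f"region {region_name(region)}: only {len(picked)} eligible adjacent "
            f"genes for {n} assigned genes"
        )
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    return picked


def build_adjacent_control_set(
    loci: Sequence[Locus],
    assignments: Sequence[Assignment],
    regions: RegionSet,
    strict: bool = False,
) -> dict[str, list[Locus]]:
    """Control sets for every region, sized to that region's assigned genes.

    Regions are processed left to right per chromosome; a gene claimed as a
    control for one region is not reused for another, so the combined control
    set is disjoint from the UR set and duplicate-free.
    """
    per_region: dict[str, int] = {}
    for a in assignments:
        if a.in_region:
            per_region[a.status] = per_region.get(a.status, 0) + 1
    controls: dict[str, list[Locus]] = {}
    claimed: set[str] = set()
    for iv in regions:
        name = region_name(iv)
        n = per_region.get(name, 0)
        if n == 0:
            continue
        picked = select_adjacent_controls(
            iv, n, loci, regions, exclude_ids=claimed, strict=strict
        )
        controls[name] = picked
        claimed.update(l.id for l in picked)
    return controls


def build_hcne_set(
    tracks: Sequence[RegionSet],
    exonic: RegionSet,
    min_len: int = 50,
) -> RegionSet:
    """Highly conserved noncoding elements from pairwise conservation tracks.

    Base-wise AND over all tracks (order-invariant), then intervals shorter
    than ``min_len`` are dropped, then intervals overlapping exonic bases by
    one base or more are dropped.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two conservation tracks to intersect")
    common = tracks[0]
    for t in tracks[1:]:
        common = intersect_sets(common, t)
    kept = [
        iv
        for iv in common
        if iv.length >= min_len and not exonic.overlaps(iv)
    ]
    return RegionSet(kept, name="hcne")
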
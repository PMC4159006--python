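"""Protein-length summaries and replication-timing score aggregation.

Replication timing arrives as signed per-probe scores (positive = earlier
replication on the source scale). A locus receives the unweighted mean of
all probes overlapping its span by at least ``min_overlap`` bases; loci with
no qualifying probe carry no score and are excluded from group statistics.
Group contrasts use the two-sided Wilcoxon/Mann-Whitney rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval
from .loci import Locus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReplicationProbe:
    interval: GenomicInterval
    score: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError(f"non-finite replication score at {self.interval}")


@dataclass
class LengthSummary:
    """Protein-length summary in amino acids; quartiles are linear-interpolated."""

    n: int
    mean: float
    median: float
    q1: float
    q3: float
    excluded_ids: list[str] = field(default_factory=list)


def summarize_lengths(
    lengths: Mapping[str, int] | Sequence[int],
    exclude: Sequence[str] = (),
) -> LengthSummary:
    """Mean/median/quartiles of protein lengths, optionally excluding entries
    by identifier (e.g. a single extreme outlier gene).

    ``lengths`` may be a mapping id -> length (required when ``exclude`` is
    used) or a bare sequence of lengths.
    """
    if isinstance(lengths, Mapping):
        excluded = [i for i in exclude if i in lengths]
        if set(exclude) - set(excluded):
            logger.warning("exclusion ids not found: %s", sorted(set(exclude) - set(excluded)))
        values = [v for k, v in lengths.items() if k not in set(excluded)]
    else:
        if exclude:
            raise ValueError("id-based exclusion requires a mapping input")
        excluded = []
        values = list(lengths)
    if not values:
        raise ValueError("no lengths remain after exclusion")
    arr = np.asarray(values, dtype=float)
    if excluded:
        logger.info("excluded %d entries: %s", len(excluded), excluded)
    return LengthSummary(
        n=len(arr),
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        q1=float(np.percentile(arr, 25)),
        q3=float(np.percentile(arr, 75)),
        excluded_ids=list(excluded),
    )


def notch_halfwidth(summary: LengthSummary) -> float:
    """Half-width of a notched-box notch: 1.58 * IQR / sqrt(n) (R convention)."""
    return 1.58 * (summary.q3 - summary.q1) / np.sqrt(summary.n)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    Exact enumeration for small tie-free samples (both n <= 50), otherwise
    the tie-corrected normal approximation with continuity correction.
    Returns (U statistic of the first sample, p).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    small = max(len(x), len(y)) <= 50
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if small and not has_ties else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# replication-score aggregation
# ---------------------------------------------------------------------------


class ProbeTrack:
    """Per-chromosome sorted probe arrays for fast span queries."""

    def __init__(self, probes: Sequence[ReplicationProbe]) -> None:
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for p in probes:
            by_chrom.setdefault(p.interval.chrom, []).append(
                (p.interval.start, p.interval.end, p.score)
            )
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, triples in by_chrom.items():
            triples.sort()
            arr = np.asarray(triples, dtype=float)
            self._by_chrom[chrom] = (
                arr[:, 0].astype(np.int64),
                arr[:, 1].astype(np.int64),
                arr[:, 2],
            )

    def mean_score(
        self, span: GenomicInterval, min_overlap: int = 5, weighted: bool = False
    ) -> float | None:
        """Mean score of probes overlapping ``span`` by >= min_overlap bases,
        unweighted by default (overlap-length-weighted behind the flag).
        Returns None when no probe qualifies."""
        entry = self._by_chrom.get(span.chrom)
        if entry is None:
            return None
        starts, ends, vals = entry
        i = int(np.searchsorted(ends, span.start, side="right"))
        j = int(np.searchsorted(starts, span.end, side="left"))
        if j <= i:
            return None
        ov = np.minimum(ends[i:j], span.end) - np.maximum(starts[i:j], span.start)
        keep = ov >= min_overlap
        if not keep.any():
            return None
        if weighted:
            w = ov[keep].astype(float)
            return float(np.average(vals[i:j][keep], weights=w))
        return float(vals[i:j][keep].mean())


def mean_replication_score(
    locus: Locus,
    probes: Sequence[ReplicationProbe] | ProbeTrack,
    min_overlap: int = 5,
    weighted: bool = False,
) -> float | None:
    """Per-locus replication score: unweighted mean over probes overlapping
    the locus span by at least ``min_overlap`` bases, or None."""
    track = probes if isinstance(probes, ProbeTrack) else ProbeTrack(probes)
    return track.mean_score(locus.span, min_overlap=min_overlap, weighted=weighted)


@dataclass
class ReplicationClassComparison:
    label: str
    n_with: int
    n_without: int
    mean_with: float
    mean_without: float
    p: float
    scores_with: np.ndarray
    scores_without: np.ndarray
    n_unscored: int


def replication_by_class(
    loci: Sequence[Locus],
    probes: Sequence[ReplicationProbe] | ProbeTrack,
    label: str,
    exclude_chrom: str | None = None,
    min_overlap: int = 5,
) -> ReplicationClassComparison:
    """Replication-score distributions for label-positive vs. -negative loci.

    ``exclude_chrom`` drops a named chromosome first (e.g. the X chromosome
    for male-derived cell data where dosage compensation advances its
    replication). Loci without a score are not counted.
    """
    track = probes if isinstance(probes, ProbeTrack) else ProbeTrack(probes)
    kept = [l for l in loci if l.chrom != exclude_chrom]
    groups: dict[bool, list[float]] = {True: [], False: []}
    unscored = 0
    for locus in kept:
        score = track.mean_score(locus.span, min_overlap=min_overlap)
        if score is None:
            unscored += 1
            continue
        groups[locus.has(label)].append(score)
    if not groups[True] or not groups[False]:
        raise ValueError(
            f"one {label} class is empty after exclusions "
            f"(+{len(groups[True])}/-{len(groups[False])} scored loci)"
        )
    _, p = wilcoxon_rank_sum(groups[True], groups[False])
    return ReplicationClassComparison(
        label=label,
        n_with=len(groups[True]),
        n_without=len(groups[False]),
        mean_with=float(np.mean(groups[True])),
        mean_without=float(np.mean(groups[False])),
        p=p,
        scores_with=np.asarray(groups[True]),
        scores_without=np.asarray(groups[False]),
        n_unscored=unscored,
    )
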
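"""Pamilo-Bianchi-Li (PBL) synonymous/nonsynonymous distances on codon
alignments.

Every codon position is classified by its degeneracy under the universal
genetic code: 4-fold when every substitution is synonymous, 0-fold when none
is, 2-fold otherwise (the 3-fold isoleucine case counts as 2-fold, and a
substitution creating a stop codon counts as nonsynonymous). Transitional
(P_i) and transversional (Q_i) difference proportions per class i feed
Kimura-type corrections

    A_i = 1/2 ln(1/(1 - 2P_i - Q_i)) - 1/4 ln(1/(1 - 2Q_i))
    B_i = 1/2 ln(1/(1 - 2Q_i))

from which

    Ks = (L2 A2 + L4 A4) / (L2 + L4) + B4
    Ka = A0 + (L0 B0 + L2 B2) / (L0 + L2)
    d4 = A4 + B4          (divergence at 4-fold degenerate sites)

Codons of a pair differing at 2-3 positions are resolved by equal-weight
averaging over all shortest substitution pathways that avoid stop codons
(the Li-Wu-Luo convention); a position whose degeneracy class differs
between the two codons splits its difference fractionally between the two
classes, and per-class site totals L_i are the mean of the two rows'
tallies. Codon columns containing a gap, an ambiguous base, or a stop codon
in either row are dropped pairwise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from math import log
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# genetic-code tables (universal code)
# ---------------------------------------------------------------------------

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_STANDARD = CodonTable.unambiguous_dna_by_id[1]

CODONS: list[str] = [a + b + c for a in BASES for b in BASES for c in BASES]
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}
#: amino acid per codon index, '*' for stops
AA: list[str] = [_STANDARD.forward_table.get(c, "*") for c in CODONS]
IS_STOP = np.array([aa == "*" for aa in AA])

_PURINES = {"A", "G"}


def is_transition(x: str, y: str) -> bool:
    """Purine<->purine or pyrimidine<->pyrimidine change."""
    return (x in _PURINES) == (y in _PURINES) and x != y


def _degeneracy(codon: str, pos: int) -> int:
    aa = AA[CODON_INDEX[codon]]
    syn = 0
    for b in BASES:
        if b == codon[pos]:
            continue
        mut = codon[:pos] + b + codon[pos + 1 :]
        if AA[CODON_INDEX[mut]] == aa:
            syn += 1
    return 4 if syn == 3 else (0 if syn == 0 else 2)


def classify_codon_sites(codon: str) -> tuple[int, int, int]:
    """Degeneracy class (0, 2 or 4) of each position of a sense codon."""
    codon = codon.upper()
    if any(b not in _BASE_INDEX for b in codon) or len(codon) != 3:
        raise ValueError(f"ambiguous or malformed codon {codon!r}")
    if AA[CODON_INDEX[codon]] == "*":
        raise ValueError(f"stop codon {codon} has no site classification")
    return tuple(_degeneracy(codon, p) for p in range(3))  # type: ignore[return-value]


#: per-codon-index class of each position; -1 for stop codons
SITE_CLASS = np.full((64, 3), -1, dtype=np.int8)
#: per-codon-index count of positions in class 0 / 2 / 4; zeros for stops
CLASS_COUNTS = np.zeros((64, 3), dtype=np.int8)
_CLASS_COL = {0: 0, 2: 1, 4: 2}
for _i, _c in enumerate(CODONS):
    if AA[_i] == "*":
        continue
    _cls = classify_codon_sites(_c)
    for _p in range(3):
        SITE_CLASS[_i, _p] = _cls[_p]
        CLASS_COUNTS[_i, _CLASS_COL[_cls[_p]]] += 1


# ---------------------------------------------------------------------------
# site-class difference counting
# ---------------------------------------------------------------------------


@dataclass
class SiteClassCounts:
    """Per-degeneracy-class site totals and observed differences for one
    sequence pair. L_i are real-valued (averaged between the two rows),
    s_i / v_i are transition / transversion difference counts (fractional
    under class-splitting and pathway averaging)."""

    L0: float = 0.0
    L2: float = 0.0
    L4: float = 0.0
    s0: float = 0.0
    s2: float = 0.0
    s4: float = 0.0
    v0: float = 0.0
    v2: float = 0.0
    v4: float = 0.0

    def __add__(self, other: "SiteClassCounts") -> "SiteClassCounts":
        return SiteClassCounts(
            *(getattr(self, f) + getattr(other, f) for f in
              ("L0", "L2", "L4", "s0", "s2", "s4", "v0", "v2", "v4"))
        )

    def L(self, cls: int) -> float:
        return getattr(self, f"L{cls}")


def _step_contribution(i_from: int, i_to: int, pos: int) -> tuple[int, int, float, float]:
    """One substitution step: returns (class_from, class_to, ts, tv) where the
    1.0 difference splits equally between the two codons' classes at pos."""
    x = CODONS[i_from][pos]
    y = CODONS[i_to][pos]
    ts = 1.0 if is_transition(x, y) else 0.0
    cf = int(SITE_CLASS[i_from, pos])
    ct = int(SITE_CLASS[i_to, pos])
    # stop codons (class -1) only appear on the rare fallback pathways;
    # inherit the sense codon's class there
    if cf < 0:
        cf = ct if ct >= 0 else 0
    if ct < 0:
        ct = cf
    return cf, ct, ts, 1.0 - ts


_PAIR_CACHE: dict[tuple[int, int], tuple[float, float, float, float, float, float]] = {}


def _pair_diff_counts(i1: int, i2: int) -> tuple[float, float, float, float, float, float]:
    """(s0, s2, s4, v0, v2, v4) for one differing sense-codon pair, averaged
    with equal weight over all shortest stop-free substitution pathways."""
    key = (i1, i2) if i1 <= i2 else (i2, i1)
    hit = _PAIR_CACHE.get(key)
    if hit is not None:
        return hit
    c1, c2 = CODONS[key[0]], CODONS[key[1]]
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    acc = np.zeros((3, 2))  # rows: class column (0/2/4); cols: (ts, tv)
    n_paths = 0
    orders = list(itertools.permutations(diff_pos))
    for allow_stops in (False, True):
        for order in orders:
            cur = c1
            steps = []
            blocked = False
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1 :]
                if not allow_stops and AA[CODON_INDEX[nxt]] == "*":
                    blocked = True
                    break
                steps.append((CODON_INDEX[cur], CODON_INDEX[nxt], p))
                cur = nxt
            if blocked:
                continue
            n_paths += 1
            for i_from, i_to, p in steps:
                cf, ct, ts, tv = _step_contribution(i_from, i_to, p)
                for cls, w in ((cf, 0.5), (ct, 0.5)):
                    acc[_CLASS_COL[cls], 0] += w * ts
                    acc[_CLASS_COL[cls], 1] += w * tv
        if n_paths:  # stop-free paths exist; no fallback needed
            break
        logger.debug("all pathways between %s and %s pass through stops", c1, c2)
    acc /= n_paths
    out = (acc[0, 0], acc[1, 0], acc[2, 0], acc[0, 1], acc[1, 1], acc[2, 1])
    _PAIR_CACHE[key] = out
    return out


def _codon_indices(row: str) -> np.ndarray:
    """Codon index per column; -1 where the codon contains a non-ACGT symbol."""
    arr = np.frombuffer(row.upper().encode("ascii"), dtype=np.uint8)
    base = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        base[arr == ord(b)] = i
    trip = base.reshape(-1, 3)
    idx = trip[:, 0] * 16 + trip[:, 1] * 4 + trip[:, 2]
    idx[(trip < 0).any(axis=1)] = -1
    return idx


def count_site_differences(row1: str, row2: str) -> SiteClassCounts:
    """Tally degeneracy-class site totals and transition/transversion
    differences between two aligned in-frame sequences.

    Codon columns with a gap, N, or stop codon in either row are skipped
    entirely (pairwise deletion).
    """
    if len(row1) != len(row2):
        raise ValueError("rows differ in length")
    if len(row1) % 3:
        raise ValueError("alignment length not divisible by 3 (frame violation)")
    i1 = _codon_indices(row1)
    i2 = _codon_indices(row2)
    valid = (i1 >= 0) & (i2 >= 0) & ~IS_STOP[np.clip(i1, 0, 63)] & ~IS_STOP[np.clip(i2, 0, 63)]
    counts = SiteClassCounts()
    tal1 = CLASS_COUNTS[i1[valid]].sum(axis=0, dtype=np.float64)
    tal2 = CLASS_COUNTS[i2[valid]].sum(axis=0, dtype=np.float64)
    counts.L0, counts.L2, counts.L4 = ((tal1 + tal2) / 2.0).tolist()
    diff_cols = np.flatnonzero(valid & (i1 != i2))
    s = np.zeros(3)
    v = np.zeros(3)
    for col in diff_cols.tolist():
        d = _pair_diff_counts(int(i1[col]), int(i2[col]))
        s += d[:3]
        v += d[3:]
    counts.s0, counts.s2, counts.s4 = s.tolist()
    counts.v0, counts.v2, counts.v4 = v.tolist()
    return counts


# ---------------------------------------------------------------------------
# PBL distance
# ---------------------------------------------------------------------------


class SaturationError(ValueError):
    """Observed differences too high for the Kimura correction (log of a
    non-positive argument) in a named degeneracy class."""


@dataclass
class PBLDistance:
    """PBL distance components. A/B/P/Q are keyed by degeneracy class."""

    P: dict[int, float]
    Q: dict[int, float]
    A: dict[int, float]
    B: dict[int, float]
    Ka: float
    Ks: float
    d4: float
    counts: SiteClassCounts | None = None


def pbl_distance(counts: SiteClassCounts) -> PBLDistance:
    """Kimura-corrected synonymous/nonsynonymous distances from class counts.

    Classes with zero sites contribute zero weight; the nonsynonymous
    estimate needs L0 + L2 > 0 and the synonymous one L2 + L4 > 0.
    """
    L = {c: counts.L(c) for c in (0, 2, 4)}
    if L[0] + L[2] <= 0:
        raise ValueError("no nondegenerate or 2-fold sites (L0 + L2 = 0)")
    if L[2] + L[4] <= 0:
        raise ValueError("no 2-fold or 4-fold sites (L2 + L4 = 0)")
    P: dict[int, float] = {}
    Q: dict[int, float] = {}
    A: dict[int, float] = {}
    B: dict[int, float] = {}
    for c in (0, 2, 4):
        s = getattr(counts, f"s{c}")
        vv = getattr(counts, f"v{c}")
        if L[c] <= 0:
            P[c] = Q[c] = A[c] = B[c] = 0.0
            continue
        P[c] = s / L[c]
        Q[c] = vv / L[c]
        a_arg = 1.0 - 2.0 * P[c] - Q[c]
        b_arg = 1.0 - 2.0 * Q[c]
        if a_arg <= 0 or b_arg <= 0:
            raise SaturationError(
                f"class {c}-fold saturated (P={P[c]:.4f}, Q={Q[c]:.4f})"
            )
        A[c] = 0.5 * log(1.0 / a_arg) - 0.25 * log(1.0 / b_arg)
        B[c] = 0.5 * log(1.0 / b_arg)
    Ks = (L[2] * A[2] + L[4] * A[4]) / (L[2] + L[4]) + B[4]
    Ka = A[0] + (L[0] * B[0] + L[2] * B[2]) / (L[0] + L[2])
    d4 = A[4] + B[4]
    return PBLDistance(P=P, Q=Q, A=A, B=B, Ka=Ka, Ks=Ks, d4=d4, counts=counts)


# ---------------------------------------------------------------------------
# codon alignments and group comparison
# ---------------------------------------------------------------------------

_ALPHABET = set("ACGTN-")


@dataclass(frozen=True)
class CodonAlignment:
    """An in-frame multiple alignment: one row per taxon, frame at column 0."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if not self.rows:
            raise ValueError("empty alignment")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("rows of unequal length")
        if width % 3:
            raise ValueError("alignment width not divisible by 3")
        for t, r in zip(self.taxa, self.rows):
            bad = set(r.upper()) - _ALPHABET
            if bad:
                raise ValueError(f"row {t} contains symbols {sorted(bad)}")

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


def concatenate_alignments(
    gene_alignments: Mapping[str, CodonAlignment], taxa: Sequence[str]
) -> CodonAlignment:
    """Join per-gene alignments into one contig, lexicographic by gene id.

    Genes whose taxon set differs from ``taxa`` are dropped with a warning.
    """
    taxa = tuple(taxa)
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    kept = 0
    for gene in sorted(gene_alignments):
        aln = gene_alignments[gene]
        if set(aln.taxa) != set(taxa):
            logger.warning("gene %s dropped: taxon set mismatch", gene)
            continue
        for t in taxa:
            parts[t].append(aln.row(t))
        kept += 1
    if kept == 0:
        raise ValueError("no gene alignment covers the requested taxon set")
    return CodonAlignment(taxa=taxa, rows=tuple("".join(parts[t]) for t in taxa))


def pairwise_distances(aln: CodonAlignment) -> pd.DataFrame:
    """All C(n,2) pairwise PBL distances of an alignment."""
    rows = []
    for i, j in itertools.combinations(range(len(aln.taxa)), 2):
        counts = count_site_differences(aln.rows[i], aln.rows[j])
        d = pbl_distance(counts)
        rows.append(
            {
                "taxon1": aln.taxa[i],
                "taxon2": aln.taxa[j],
                "d4": d.d4,
                "Ka": d.Ka,
                "Ks": d.Ks,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """Paired distances for two gene groups over the same taxon pairs."""

    distances: pd.DataFrame  # long form: group, taxon1, taxon2, d4, Ka, Ks
    paired: pd.DataFrame  # one row per taxon pair with <metric>_<group> columns
    mean_ratio: dict[str, float]  # metric -> mean focal/baseline ratio over pairs


def concatenate_and_compare(
    gene_alignments: Mapping[str, CodonAlignment],
    groups: Mapping[str, Sequence[str]],
    taxa: Sequence[str],
) -> GroupComparison:
    """Concatenate each group's genes and compare pairwise distances.

    The first two group names (insertion order) act as focal and baseline
    for the paired table and the mean focal/baseline ratios of d4, Ka and Ks
    over all taxon pairs.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups to compare")
    frames = []
    for name in names:
        ids = list(groups[name])
        if not ids:
            raise ValueError(f"group {name!r} is empty")
        sub = {g: gene_alignments[g] for g in ids if g in gene_alignments}
        missing = set(ids) - set(sub)
        if missing:
            logger.warning("group %s: %d genes lack alignments", name, len(missing))
        contig = concatenate_alignments(sub, taxa)
        df = pairwise_distances(contig)
        df.insert(0, "group", name)
        frames.append(df)
    distances = pd.concat(frames, ignore_index=True)
    focal, baseline = names[0], names[1]
    left = distances[distances.group == focal].set_index(["taxon1", "taxon2"])
    right = distances[distances.group == baseline].set_index(["taxon1", "taxon2"])
    paired = left[["d4", "Ka", "Ks"]].join(
        right[["d4", "Ka", "Ks"]], lsuffix=f"_{focal}", rsuffix=f"_{baseline}"
    ).reset_index()
    mean_ratio = {
        m: float((left[m] / right[m]).mean()) for m in ("d4", "Ka", "Ks")
    }
    return GroupComparison(distances=distances, paired=paired, mean_ratio=mean_ratio)
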
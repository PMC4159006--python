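"""Observed/expected enrichment statistics for genes, conserved elements and
noncoding RNAs in underreplicated regions.

All expectations are length- or fraction-proportional nulls: for gene labels
the genome-wide fraction of label-positive genes, for elements the
genome-wide per-Mb density of each annotation category multiplied by the
category length inside the regions. Significance uses a two-cell df=1
chi-squared goodness-of-fit (observed inside vs. observed outside against the
proportional split), or a Pearson 2x2 chi-square without continuity
correction where two groups are contrasted. No multiple-testing correction
is applied; the number of tests performed is reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assignment import Assignment
from .intervals import AnnotationPartition, GenomicInterval, RegionSet, coverage_fraction
from .loci import Locus

logger = logging.getLogger(__name__)

CATEGORIES = ("exonic", "intronic", "intergenic")

Membership = Literal["midpoint", "any", "half"]


@dataclass
class EnrichmentResult:
    """One observed-vs-expected comparison.

    Both direction ratios are reported (``obs_over_exp`` and
    ``exp_over_obs``) because published tables print whichever exceeds one;
    ``exp_over_obs`` is None when observed is zero.
    """

    category: str
    observed: float
    expected: float
    total: int
    chi2: float
    p: float
    density_per_mb: float | None = None

    @property
    def obs_over_exp(self) -> float:
        return self.observed / self.expected

    @property
    def exp_over_obs(self) -> float | None:
        return self.expected / self.observed if self.observed > 0 else None

    def as_dict(self) -> dict:
        return {
            "category": self.category,
            "observed": self.observed,
            "expected": self.expected,
            "total": self.total,
            "obs_over_exp": self.obs_over_exp,
            "exp_over_obs": self.exp_over_obs,
            "chi2": self.chi2,
            "p": self.p,
            "density_per_mb": self.density_per_mb,
        }


def gof_chi_squared(
    observed: float, expected: float, total: float, category: str = ""
) -> EnrichmentResult:
    """Two-cell goodness-of-fit chi-squared, df = 1, no continuity correction.

    The two cells are (inside, outside): X^2 = (O-E)^2/E + (O-E)^2/(T-E),
    since the outside residual is the mirror of the inside one. The p-value
    is the upper tail of chi-squared with one degree of freedom.
    """
    if not (0 <= observed <= total):
        raise ValueError(f"observed {observed} outside [0, total={total}]")
    if not (0 < expected < total):
        raise ValueError(f"expected must lie strictly inside (0, total), got {expected}")
    chi2 = (observed - expected) ** 2 / expected + (observed - expected) ** 2 / (
        total - expected
    )
    p = float(stats.chi2.sf(chi2, df=1))
    return EnrichmentResult(
        category=category, observed=observed, expected=expected, total=int(total),
        chi2=float(chi2), p=p,
    )


def pearson_chi2_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table [[a, b], [c, d]], df = 1, no Yates
    correction: X^2 = n(ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)]."""
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("2x2 table has a zero margin")
    chi2 = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


# ---------------------------------------------------------------------------
# gene label enrichment (Table-1 style)
# ---------------------------------------------------------------------------


def gene_class_enrichment(
    assignments: Sequence[Assignment],
    loci: Sequence[Locus],
    label: str,
    strata: str | None = None,
) -> pd.DataFrame:
    """Enrichment/depletion of a label flag among region-assigned genes.

    The expected count in each stratum is the genome-wide fraction of
    label-positive genes within that stratum times the number of
    region-assigned genes in the stratum. With ``strata`` set (e.g.
    ``testis_specific``), the strata are "all", the flag-positive stratum,
    and "other" — the latter two restricted to loci with known expression.
    """
    by_id = {l.id: l for l in loci}
    inside_ids = {a.locus_id for a in assignments if a.in_region}

    def stratum_members(name: str) -> list[Locus]:
        if name == "all":
            return list(loci)
        if strata is None:
            raise ValueError("no strata flag configured")
        known = [l for l in loci if l.has("expression_known")]
        if name == strata:
            return [l for l in known if l.has(strata)]
        return [l for l in known if not l.has(strata)]

    rows = []
    names = ["all"] if strata is None else ["all", strata, "other"]
    for name in names:
        members = stratum_members(name)
        n_genome = len(members)
        n_pos_genome = sum(1 for l in members if l.has(label))
        inside = [l for l in members if l.id in inside_ids]
        n_inside = len(inside)
        observed = sum(1 for l in inside if l.has(label))
        if n_genome == 0 or n_inside == 0:
            logger.warning("stratum %s empty, omitted", name)
            continue
        expected = n_pos_genome / n_genome * n_inside
        if not (0 < expected < n_inside):
            logger.warning("stratum %s degenerate null (expected=%s), omitted", name, expected)
            continue
        res = gof_chi_squared(observed, expected, n_inside, category=name)
        rows.append(
            {
                "label": label,
                "stratum": name,
                "genes_in_regions": n_inside,
                "observed": observed,
                "expected": round(expected, 1),
                "obs_over_exp": res.obs_over_exp,
                "exp_over_obs": res.exp_over_obs,
                "chi2": res.chi2,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# element enrichment (Table-2 style)
# ---------------------------------------------------------------------------


def _element_in_regions(iv: GenomicInterval, regions: RegionSet, rule: Membership) -> bool:
    if rule == "midpoint":
        return regions.contains_point(iv.chrom, iv.midpoint)
    if rule == "any":
        return regions.overlaps(iv)
    if rule == "half":
        return coverage_fraction(iv, regions) >= 0.5
    raise ValueError(f"unknown membership rule {rule!r}")


def element_enrichment(
    elements: RegionSet | Sequence[GenomicInterval],
    partition: AnnotationPartition,
    regions: RegionSet,
    membership: Membership = "midpoint",
    categories: Sequence[str] = ("intronic", "intergenic"),
    track: str = "",
) -> list[EnrichmentResult]:
    """Length-proportional enrichment of elements inside regions, per category.

    Each element is assigned to the annotation category of its midpoint
    (configurable to any-overlap or >=50%-coverage membership; midpoint keeps
    expected counts exactly length-proportional). The genome-wide per-Mb
    density of each category times the category length inside the regions
    gives the expected count; significance is the two-cell goodness-of-fit
    against the genome-wide element count of that category.
    """
    elems = list(elements)
    results: list[EnrichmentResult] = []
    for cat in categories:
        cat_set = partition.get(cat)
        members = [
            iv for iv in elems if partition.category_of_point(iv.chrom, iv.midpoint) == cat
        ]
        total = len(members)
        len_genome = cat_set.total_length()
        from .intervals import intersect_sets

        len_inside = intersect_sets(cat_set, regions).total_length()
        if len_inside == 0 or len_genome == 0:
            logger.warning("category %s has zero length inside regions, skipped", cat)
            continue
        density = total / (len_genome / 1e6)
        expected = density * (len_inside / 1e6)
        observed = sum(1 for iv in members if _element_in_regions(iv, regions, membership))
        if total == 0 or not (0 < expected < total):
            logger.warning("category %s degenerate (expected=%s of %s), skipped", cat, expected, total)
            continue
        res = gof_chi_squared(observed, expected, total, category=f"{track}:{cat}" if track else cat)
        res.density_per_mb = density
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# noncoding RNA census (Table-3 style) and lincRNA summary
# ---------------------------------------------------------------------------


@dataclass
class LincRNASummary:
    n_total: int
    n_in_regions: int
    fraction_in_regions: float
    mean_length_inside: float
    mean_length_outside: float
    region_bases_covered_fraction: float
    intergenic_region_bases_covered_fraction: float


def majority_category(iv: GenomicInterval, partition: AnnotationPartition) -> str:
    """Annotation category covering the majority of the span; ties resolved
    by exonic > intronic > intergenic precedence."""
    from .intervals import intersect_sets

    single = RegionSet([iv])
    best_cat, best_len = "intergenic", -1
    for cat in CATEGORIES:  # precedence order: first wins ties
        ov = intersect_sets(partition.get(cat), single).total_length()
        if ov > best_len:
            best_cat, best_len = cat, ov
    return best_cat


def ncrna_census(
    ncrna_loci: Sequence[Locus],
    partition: AnnotationPartition,
    regions: RegionSet,
    linc_threshold: float = 0.5,
) -> tuple[pd.DataFrame, LincRNASummary | None]:
    """Short ncRNA observed/expected counts per annotation category, plus a
    lincRNA summary.

    Short classes (miRNA, snoRNA, tRNA) are assigned one category by the
    majority of their span; a short ncRNA counts as inside the regions when
    at least half of its span is covered. Expected counts scale the
    genome-wide class total in a category by the fraction of that category's
    bases lying inside the regions. lincRNAs use the 50%-overlap rule and
    report counts, mean occupied span inside vs. outside, and the fraction
    of region/intergenic bases they cover.
    """
    from .intervals import intersect_sets

    short_classes = ("miRNA", "snoRNA", "tRNA")
    cat_len_genome = {c: partition.get(c).total_length() for c in CATEGORIES}
    cat_len_inside = {
        c: intersect_sets(partition.get(c), regions).total_length() for c in CATEGORIES
    }
    rows = []
    for cls in short_classes:
        members = [l for l in ncrna_loci if l.ncrna_class == cls]
        for cat in CATEGORIES:
            in_cat = [l for l in members if majority_category(l.span, partition) == cat]
            observed = sum(
                1 for l in in_cat if coverage_fraction(l.span, regions) >= linc_threshold
            )
            frac = (
                cat_len_inside[cat] / cat_len_genome[cat] if cat_len_genome[cat] else 0.0
            )
            expected = len(in_cat) * frac
            rows.append(
                {
                    "class": cls,
                    "category": cat,
                    "genome_count": len(in_cat),
                    "observed": observed,
                    "expected": expected,
                    "obs_over_exp": observed / expected if expected > 0 else None,
                    "exp_over_obs": expected / observed if observed > 0 else None,
                }
            )
    table = pd.DataFrame(rows)

    lincs = [l for l in ncrna_loci if l.ncrna_class == "lincRNA"]
    summary = None
    if lincs:
        inside = [l for l in lincs if coverage_fraction(l.span, regions) >= linc_threshold]
        outside = [l for l in lincs if coverage_fraction(l.span, regions) < linc_threshold]
        linc_set = RegionSet([l.span for l in lincs])
        covered_in_regions = intersect_sets(linc_set, regions).total_length()
        intergenic_in_regions = intersect_sets(partition.intergenic, regions)
        covered_intergenic = intersect_sets(linc_set, intergenic_in_regions).total_length()
        region_len = regions.total_length()
        ig_len = intergenic_in_regions.total_length()
        summary = LincRNASummary(
            n_total=len(lincs),
            n_in_regions=len(inside),
            fraction_in_regions=len(inside) / len(lincs),
            mean_length_inside=float(np.mean([l.span.length for l in inside])) if inside else float("nan"),
            mean_length_outside=float(np.mean([l.span.length for l in outside])) if outside else float("nan"),
            region_bases_covered_fraction=covered_in_regions / region_len if region_len else 0.0,
            intergenic_region_bases_covered_fraction=covered_intergenic / ig_len if ig_len else 0.0,
        )
    return table, summary
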
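"""Chi-squared machinery and observed/expected bookkeeping for genes,
elements and noncoding RNAs."""

import numpy as np
import pytest
from scipy import stats

from underrep.assignment import assign_loci
from underrep.enrichment import (
    element_enrichment,
    gene_class_enrichment,
    gof_chi_squared,
    ncrna_census,
    pearson_chi2_2x2,
)
from underrep.intervals import GenomicInterval, RegionSet, partition_annotation
from underrep.loci import Isoform, Locus


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestGofChiSquared:
    def test_observed_equals_expected(self):
        res = gof_chi_squared(50, 50.0, 200)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_hand_computed_two_cell_form(self):
        # X^2 = (10-5)^2/5 + (10-5)^2/15 = 5 + 5/3
        res = gof_chi_squared(10, 5.0, 20)
        assert res.chi2 == pytest.approx(5 + 5 / 3)
        assert res.p == pytest.approx(stats.chi2.sf(5 + 5 / 3, 1))

    def test_degenerate_null_rejected(self):
        with pytest.raises(ValueError):
            gof_chi_squared(5, 0.0, 10)
        with pytest.raises(ValueError):
            gof_chi_squared(5, 10.0, 10)
        with pytest.raises(ValueError):
            gof_chi_squared(11, 5.0, 10)

    def test_ratio_fields_are_reciprocal(self):
        res = gof_chi_squared(40, 80.0, 400)
        assert res.obs_over_exp * res.exp_over_obs == pytest.approx(1.0)

    def test_matches_scipy_chisquare_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            total = int(rng.integers(10, 5000))
            expected = float(rng.uniform(0.5, total - 0.5))
            observed = int(rng.integers(0, total + 1))
            res = gof_chi_squared(observed, expected, total)
            ref = stats.chisquare([observed, total - observed], [expected, total - expected])
            assert res.chi2 == pytest.approx(ref.statistic)
            assert res.p == pytest.approx(ref.pvalue)


class TestPearson2x2:
    def test_published_est_table(self):
        chi2, p = pearson_chi2_2x2(53, 11, 786, 83)
        assert chi2 == pytest.approx(3.84, abs=0.01)
        assert p == pytest.approx(0.05, abs=0.001)

    def test_proportional_rows_give_zero(self):
        chi2, _ = pearson_chi2_2x2(10, 20, 30, 60)
        assert chi2 == pytest.approx(0.0)

    def test_perfect_separation(self):
        chi2, p = pearson_chi2_2x2(10, 0, 0, 10)
        assert chi2 == pytest.approx(20.0)
        assert p == pytest.approx(stats.chi2.sf(20, 1))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2_2x2(0, 0, 5, 5)

    def test_matches_scipy_without_correction_on_random_tables(self):
        rng = np.random.default_rng(2)
        n = 0
        while n < 1000:
            a, b, c, d = rng.integers(0, 50, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            n += 1
            chi2, p = pearson_chi2_2x2(int(a), int(b), int(c), int(d))
            ref = stats.chi2_contingency([[a, b], [c, d]], correction=False)
            assert chi2 == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)


def grid_loci(n, length, label_flags):
    """n equally spaced single-exon loci across [0, length)."""
    out = []
    step = length // n
    for k in range(n):
        s = k * step + step // 4
        span = GenomicInterval("chr1", s, s + step // 2)
        out.append(
            Locus(
                id=f"g{k:04d}",
                chrom="chr1",
                isoforms=(Isoform(name="RA", span=span, exons=(span,)),),
                labels=frozenset(label_flags(k)),
            )
        )
    return out


class TestGeneClassEnrichment:
    def test_null_label_gives_unit_ratio(self):
        rng = np.random.default_rng(3)
        loci = grid_loci(
            1000, 1_000_000,
            lambda k: {"human_homolog"} if rng.random() < 0.4 else set(),
        )
        regions = RegionSet([iv(0, 250_000)])
        assignments = assign_loci(loci, regions)
        table = gene_class_enrichment(assignments, loci, "human_homolog")
        row = table.iloc[0]
        # expected is the genome-wide fraction; under the null obs ~ expected
        assert row.observed == pytest.approx(row.expected, rel=0.25)

    def test_planted_depletion_recovered(self):
        rng = np.random.default_rng(4)
        regions = RegionSet([iv(0, 250_000)])
        loci = grid_loci(1000, 1_000_000, lambda k: set())
        assignments = assign_loci(loci, regions)
        inside = {a.locus_id for a in assignments if a.in_region}
        for locus in loci:
            p = 0.1 if locus.id in inside else 0.45
            if rng.random() < p:
                locus.labels = frozenset({"human_homolog"})
        table = gene_class_enrichment(assignments, loci, "human_homolog")
        row = table.iloc[0]
        n_in = len(inside)
        # planted exp/obs: mixture fraction over 0.1 -> roughly 3.6; allow
        # generous sampling noise at n=250 inside genes
        assert row.exp_over_obs > 2.0
        assert row.p < 1e-6

    def test_strata_layout(self, small_bundle):
        assignments = assign_loci(small_bundle.loci, small_bundle.regions)
        table = gene_class_enrichment(
            assignments, small_bundle.loci, "human_homolog", strata="testis_specific"
        )
        assert list(table.stratum) == ["all", "testis_specific", "other"]
        # strata are restricted to loci with known expression
        known = [l for l in small_bundle.loci if l.has("expression_known")]
        inside = {a.locus_id for a in assignments if a.in_region}
        n_testis = sum(1 for l in known if l.has("testis_specific") and l.id in inside)
        assert table.set_index("stratum").loc["testis_specific", "genes_in_regions"] == n_testis


class TestElementEnrichment:
    @staticmethod
    def _setup(rng, density_in=100.0, density_out=100.0):
        length = 2_000_000
        loci = grid_loci(40, length, lambda k: set())
        regions = RegionSet([iv(0, 400_000)])
        partition = partition_annotation(loci, [iv(0, length)])
        elements = []
        # place elements into intergenic space at the two densities
        from underrep.intervals import intersect_sets, subtract_sets

        for space, dens in (
            (intersect_sets(partition.intergenic, regions), density_in),
            (subtract_sets(partition.intergenic, regions), density_out),
        ):
            for seg in space:
                n = rng.poisson(dens * seg.length / 1e6)
                for _ in range(n):
                    if seg.length < 60:
                        continue
                    s = seg.start + int(rng.integers(0, seg.length - 50))
                    elements.append(iv(s, s + 50))
        return elements, partition, regions

    def test_uniform_elements_ratio_near_one(self):
        rng = np.random.default_rng(5)
        elements, partition, regions = self._setup(rng)
        (res,) = element_enrichment(elements, partition, regions, categories=("intergenic",))
        assert res.obs_over_exp == pytest.approx(1.0, abs=0.25)

    def test_expected_mass_is_a_partition(self):
        """Expected counts over inside + outside sum to the category total."""
        rng = np.random.default_rng(6)
        elements, partition, regions = self._setup(rng, density_in=200.0)
        (res_in,) = element_enrichment(elements, partition, regions, categories=("intergenic",))
        from underrep.intervals import complement

        chroms = [iv(0, 2_000_000)]
        outside = complement(regions, chroms)
        (res_out,) = element_enrichment(elements, partition, outside, categories=("intergenic",))
        assert res_in.expected + res_out.expected == pytest.approx(res_in.total)
        assert res_in.observed + res_out.observed == res_in.total

    def test_midpoint_vs_alternative_membership_rules(self):
        loci = grid_loci(4, 100_000, lambda k: set())
        partition = partition_annotation(loci, [iv(0, 100_000)])
        regions = RegionSet([iv(0, 1_010)])
        straddler = iv(1_000, 1_040)  # midpoint 1020 outside [0,1010)
        for rule, expect_obs in (("midpoint", 0), ("any", 1), ("half", 0)):
            (res,) = element_enrichment(
                [straddler] + [iv(50_000 + 100 * k, 50_020 + 100 * k) for k in range(20)],
                partition,
                regions,
                membership=rule,
                categories=("intergenic",),
            )
            assert res.observed == expect_obs


class TestNcRNACensus:
    def test_planted_snorna_depletion(self, small_bundle):
        partition = partition_annotation(small_bundle.loci, small_bundle.chromosomes)
        table, linc = ncrna_census(small_bundle.ncrna, partition, small_bundle.regions)
        sno = table[table["class"] == "snoRNA"]
        assert sno.observed.sum() == 0  # planted complete depletion
        assert sno.expected.sum() > 0
        assert linc is not None and linc.n_total == len(
            [l for l in small_bundle.ncrna if l.ncrna_class == "lincRNA"]
        )

    def test_census_counts_every_ncrna_once(self, small_bundle):
        partition = partition_annotation(small_bundle.loci, small_bundle.chromosomes)
        table, _ = ncrna_census(small_bundle.ncrna, partition, small_bundle.regions)
        for cls in ("miRNA", "snoRNA", "tRNA"):
            n_class = sum(1 for l in small_bundle.ncrna if l.ncrna_class == cls)
            assert table[table["class"] == cls].genome_count.sum() == n_class
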
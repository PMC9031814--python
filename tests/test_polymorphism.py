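"""Per-gene diversity tabulation, window pi, feature labels, recombination."""

import itertools

import numpy as np
import pytest

from ratediv.io_formats import FeatureInterval, GeneticMap, VariantRecord
from ratediv.polymorphism import (
    WindowDiversity,
    assign_window_feature,
    attach_map_positions,
    haldane_fraction,
    interpolate_cM,
    singleton_allele_frequency,
    tabulate_gene_variation,
    window_pi,
    window_recombination,
)


def test_singleton_allele_frequency_cohort():
    assert singleton_allele_frequency(2504) == pytest.approx(1 / 5008)


class TestGeneTabulation:
    def test_basic_counts(self):
        genes = [FeatureInterval("chr1", 0, 1000, "exon", "G1")]
        variants = [
            VariantRecord("chr1", 10, 1, 10),
            VariantRecord("chr1", 20, 5, 10),
            VariantRecord("chr1", 30, 8, 10),
        ]
        tab = tabulate_gene_variation(variants, genes)
        row = tab.iloc[0]
        assert row.K == 3 and row.singletons == 1
        assert row.q == pytest.approx(0.003)

    def test_fixed_sites_not_segregating(self):
        genes = [FeatureInterval("chr1", 0, 1000, "exon", "G1")]
        variants = [
            VariantRecord("chr1", 10, 0, 10),
            VariantRecord("chr1", 20, 10, 10),
        ]
        tab = tabulate_gene_variation(variants, genes)
        assert tab.iloc[0].K == 0

    def test_reference_singleton_counts(self):
        """AC = AN - 1 leaves the reference on one chromosome: a singleton."""
        genes = [FeatureInterval("chr1", 0, 100, "exon", "G1")]
        variants = [VariantRecord("chr1", 5, 9, 10)]
        tab = tabulate_gene_variation(variants, genes)
        assert tab.iloc[0].singletons == 1

    def test_multiallelic_site_counts_once_for_K(self):
        genes = [FeatureInterval("chr1", 0, 100, "exon", "G1")]
        variants = [
            VariantRecord("chr1", 5, 3, 10),
            VariantRecord("chr1", 5, 1, 10),  # second alt at same site
        ]
        tab = tabulate_gene_variation(variants, genes)
        assert tab.iloc[0].K == 1
        assert tab.iloc[0].singletons == 1  # an allele with count 1 exists

    def test_gene_length_is_union_of_intervals(self):
        genes = [
            FeatureInterval("chr1", 0, 100, "exon", "G1"),
            FeatureInterval("chr1", 50, 200, "exon", "G1"),  # overlapping
        ]
        tab = tabulate_gene_variation([], genes)
        assert tab.iloc[0].L == 200

    def test_brute_force_recount(self):
        """K matches a per-site brute-force recount on a synthetic cohort."""
        rng = np.random.default_rng(8)
        genes = [
            FeatureInterval("chr1", 0, 500, "exon", "G1"),
            FeatureInterval("chr1", 700, 1500, "exon", "G2"),
        ]
        variants = [
            VariantRecord("chr1", int(p) + 1, int(rng.integers(0, 11)), 10)
            for p in rng.choice(2000, size=120, replace=False)
        ]
        tab = tabulate_gene_variation(variants, genes).set_index("gene_id")
        for gid, (s, e) in [("G1", (0, 500)), ("G2", (700, 1500))]:
            brute = sum(
                1 for v in variants if s <= v.pos - 1 < e and 0 < v.alt_allele_count < 10
            )
            assert tab.loc[gid].K == brute

    def test_de_novo_and_x_flag(self):
        genes = [FeatureInterval("chrX", 0, 100, "exon", "GX")]
        dn = [VariantRecord("chrX", 5, 1, 2, is_de_novo=True)]
        tab = tabulate_gene_variation([], genes, denovo=dn)
        assert tab.iloc[0].de_novo == 1
        assert bool(tab.iloc[0].is_X)

    def test_label_permutation_invariance(self):
        """q depends only on allele counts, not on which samples carry them."""
        genes = [FeatureInterval("chr1", 0, 100, "exon", "G1")]
        v1 = [VariantRecord("chr1", 5, 3, 10), VariantRecord("chr1", 9, 7, 10)]
        v2 = [VariantRecord("chr1", 9, 7, 10), VariantRecord("chr1", 5, 3, 10)]
        assert (
            tabulate_gene_variation(v1, genes).iloc[0].q
            == tabulate_gene_variation(v2, genes).iloc[0].q
        )


class TestWindowPi:
    def test_single_site_half_frequency(self):
        variants = [VariantRecord("chr1", 500, 1, 2)]
        (w,) = window_pi(variants, chrom_length=1000)
        assert w.pi == pytest.approx((2 * 0.25 * 2) / 1000)

    def test_empty_window(self):
        windows = window_pi([], chrom_length=3000)
        assert len(windows) == 3
        assert all(w.pi == 0 for w in windows)

    def test_matches_pairwise_enumeration(self):
        """pi equals the mean pairwise difference over all haplotype pairs."""
        rng = np.random.default_rng(4)
        n = 6
        haplos = rng.integers(0, 2, size=(n, 10))  # 10 segregating sites
        variants = [
            VariantRecord("chr1", 100 + j, int(haplos[:, j].sum()), n)
            for j in range(10)
        ]
        (w,) = window_pi(variants, chrom_length=1000)
        diffs = [
            (haplos[i] != haplos[j]).sum()
            for i, j in itertools.combinations(range(n), 2)
        ]
        expected = np.mean(diffs) / 1000
        assert w.pi == pytest.approx(expected)

    def test_heterozygosity_conservation(self):
        """Sum over windows of pi*width equals the per-site heterozygosity sum."""
        rng = np.random.default_rng(5)
        variants = [
            VariantRecord("chr1", int(p) + 1, int(rng.integers(1, 10)), 10)
            for p in rng.choice(5000, 60, replace=False)
        ]
        windows = window_pi(variants, chrom_length=5000)
        total_window = sum(w.pi * 1000 for w in windows)
        total_site = sum(
            2 * (v.alt_allele_count / 10) * (1 - v.alt_allele_count / 10) * 10 / 9
            for v in variants
        )
        assert total_window == pytest.approx(total_site)


class TestFeatureAssignment:
    def _windows(self, starts):
        return [WindowDiversity("chr1", s, 0.0) for s in starts]

    def test_window_inside_exon(self):
        feats = [FeatureInterval("chr1", 0, 5000, "exon", "G1")]
        (w,) = assign_window_feature(self._windows([1000]), feats)
        assert w.feature == "exon"

    def test_far_window_is_intergenic(self):
        feats = [FeatureInterval("chr1", 0, 1000, "exon", "G1")]
        (w,) = assign_window_feature(self._windows([151_000]), feats)
        assert w.feature == "intergenic"

    def test_majority_rule(self):
        feats = [
            FeatureInterval("chr1", 0, 400, "exon", "G1"),
            FeatureInterval("chr1", 400, 1000, "intron", "G1"),
        ]
        (w,) = assign_window_feature(self._windows([0]), feats)
        assert w.feature == "intron"  # 600 bp intron vs 400 bp exon

    def test_tie_precedence_exon_wins(self):
        feats = [
            FeatureInterval("chr1", 0, 500, "intron", "G1"),
            FeatureInterval("chr1", 500, 1000, "exon", "G1"),
        ]
        (w,) = assign_window_feature(self._windows([0]), feats)
        assert w.feature == "exon"

    def test_labels_always_in_enum_and_intergenic_far(self):
        rng = np.random.default_rng(6)
        feats = [
            FeatureInterval("chr1", int(s), int(s) + 800, f, "G%d" % i)
            for i, (s, f) in enumerate(
                zip(rng.choice(300_000, 12, replace=False),
                    rng.choice(["exon", "utr5", "utr3", "intron"], 12))
            )
        ]
        windows = assign_window_feature(self._windows(range(0, 400_000, 10_000)), feats)
        bounds = [b for f in feats for b in (f.start, f.end)]
        for w in windows:
            assert w.feature in ("exon", "utr5", "utr3", "intron", "intergenic")
            if w.feature == "intergenic":
                dist = min(
                    min(abs(b - p) for b in bounds)
                    for p in (w.start, w.start + 999)
                )
                assert dist > 100_000 or all(
                    not (f.start < w.start + 1000 and w.start < f.end) for f in feats
                )


class TestRecombination:
    def setup_method(self):
        self.map = GeneticMap("chr1", [0, 1_000_000], [0.0, 1.0])

    def test_zero_at_own_midpoint(self):
        w = WindowDiversity("chr1", 10_000, 0.0)
        assert window_recombination(w, self.map, 10_500) == 0.0

    def test_closed_form_small_distance(self):
        # 0.01 cM -> R = 0.5 (1 - e^{-0.0002})
        w = WindowDiversity("chr1", 0, 0.0)  # midpoint 500 -> 0.0005 cM
        target = 10_500  # 0.0105 cM; d = 0.01 cM
        r = window_recombination(w, self.map, target)
        assert r == pytest.approx(0.5 * (1 - np.exp(-0.0002)), rel=1e-9)

    def test_saturates_at_half(self):
        big = GeneticMap("chr1", [0, 1_000_000], [0.0, 10_000.0])
        w = WindowDiversity("chr1", 0, 0.0)
        assert window_recombination(w, big, 999_999) == pytest.approx(0.5, abs=1e-6)

    def test_linear_extrapolation(self):
        assert interpolate_cM(self.map, 2_000_000) == pytest.approx(2.0)
        assert interpolate_cM(self.map, -1_000_000) == pytest.approx(-1.0)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            interpolate_cM(GeneticMap("chr1", [], []), 100)

    def test_haldane_bounds(self):
        for d in [0.0, 0.01, 1.0, 50.0, 300.0]:
            assert 0 <= haldane_fraction(d) < 0.5

    def test_attach_map_positions(self):
        ws = attach_map_positions([WindowDiversity("chr1", 0, 0.0)], self.map)
        assert ws[0].map_cM == pytest.approx(0.0005)
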
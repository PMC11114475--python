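import math

import numpy as np
import pytest
from scipy import stats

from symbiopsi.genome_features import (
    compare_feature,
    feature_table,
    gc_content,
    gc_summary,
    group_means,
    intron_position_profile,
    rank_sum_test,
)
from symbiopsi.io_formats import GeneModel, GroupAssignment, Interval, SequenceRecord

from oracles import rank_sum_exact_oracle


def gene(exon_coords, strand="+", scaffold="s", gene_id="g", taxon="T"):
    exons = [Interval(scaffold, a, b, strand) for a, b in exon_coords]
    return GeneModel(gene_id, taxon, scaffold, strand, exons, list(exons))


class TestGc:
    @pytest.mark.parametrize(
        "seq,expect",
        [("ATGC", 0.5), ("GGCC", 1.0), ("ANGC", 2 / 3), ("AATT", 0.0)],
    )
    def test_values(self, seq, expect):
        assert gc_content(seq) == pytest.approx(expect)

    def test_all_n_is_nan(self):
        assert math.isnan(gc_content("NNNN"))

    def test_concatenation_is_length_weighted_mean(self):
        rng = np.random.default_rng(0)
        parts = ["".join(rng.choice(list("ACGT"), size=n)) for n in (50, 150, 77)]
        whole = gc_content("".join(parts))
        weighted = sum(gc_content(p) * len(p) for p in parts) / sum(
            len(p) for p in parts
        )
        assert whole == pytest.approx(weighted, abs=1e-12)


class TestFeatureTable:
    genome = [SequenceRecord("s", "ACGT" * 25)]

    def test_single_exon_gene(self):
        (row,) = feature_table([gene([(0, 12)])], self.genome)
        assert row.n_introns == 0
        assert row.intron_fraction == 0.0
        assert row.exon_fraction == 1.0

    def test_two_exon_gene(self):
        (row,) = feature_table([gene([(0, 10), (20, 30)])], self.genome)
        assert row.gene_length == 30
        assert row.intron_lengths == (10,)
        assert row.intron_fraction == pytest.approx(1 / 3)
        assert row.exon_fraction == pytest.approx(2 / 3)

    def test_exon_plus_intron_equals_gene_length(self, small_cohort):
        for taxon, models in small_cohort.annotations.items():
            rows = feature_table(models, small_cohort.genomes[taxon])
            for m, r in zip(models, rows):
                exon_total = sum(iv.length for iv in m.exons)
                assert exon_total + sum(r.intron_lengths) == r.gene_length
                assert r.exon_fraction + r.intron_fraction == pytest.approx(1.0)

    def test_gc_summary_regions(self):
        genome = [SequenceRecord("s", "GGGGGGGGGG" + "AAAAAAAAAA" + "GCGCGCGCGC")]
        m = gene([(0, 10), (20, 30)])
        s = gc_summary(genome, [m], taxon="x")
        assert s.cds_gc == pytest.approx(1.0)  # GGG.. + GCGC..
        assert s.intron_gc == pytest.approx(0.0)
        assert s.genome_gc == pytest.approx(2 / 3)


class TestIntronProfile:
    def test_midpoint_in_middle_bin(self):
        m = gene([(0, 40), (60, 100)])  # intron 40..60, midpoint 50 of 100
        profile = intron_position_profile([m], n_bins=5)
        assert list(profile) == [0, 0, 1, 0, 0]

    def test_minus_strand_flips_to_five_prime(self):
        # intron near genomic end; on '-' strand that is the 5' end
        m = gene([(0, 80), (90, 100)], strand="-")
        profile = intron_position_profile([m], n_bins=5)
        assert list(profile) == [1, 0, 0, 0, 0]

    def test_uniform_null_is_flat(self, small_cohort):
        """Introns placed uniformly along genes give a flat profile
        (chi-square not significant at 0.01)."""
        models = [m for ms in small_cohort.annotations.values() for m in ms]
        profile = intron_position_profile(models, n_bins=5)
        assert profile.sum() >= 100
        chi = stats.chisquare(profile)
        assert chi.pvalue > 0.01


class TestRankSum:
    def test_exact_small_sample(self):
        """{1,2,3} vs {4,5,6}: exact two-sided p = 0.1, the most extreme
        of the C(6,3)=20 rank splits, doubled."""
        p, method = rank_sum_test(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert method == "exact"
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(rank_sum_exact_oracle([1, 2, 3], [4, 5, 6]))

    def test_identical_samples_degenerate(self):
        p, method = rank_sum_test(np.array([2.0, 2, 2]), np.array([2.0, 2]))
        assert p == 1.0 and method == "degenerate"

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=10), rng.normal(1.0, size=8)
        p1, _ = rank_sum_test(x, y)
        p2, _ = rank_sum_test(y, x)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_ties_use_corrected_asymptotic(self):
        x = np.array([1.0, 2, 2, 3])
        y = np.array([2.0, 4, 5])
        p, method = rank_sum_test(x, y)
        assert method == "asymptotic" and 0 < p <= 1

    def test_exact_matches_enumeration_for_several_sizes(self):
        rng = np.random.default_rng(1)
        for n, m in [(3, 3), (4, 5), (6, 6), (8, 7)]:
            pooled = rng.permutation(100)[: n + m].astype(float)
            x, y = pooled[:n], pooled[n:]
            p, method = rank_sum_test(x, y)
            assert method == "exact"
            assert p == pytest.approx(rank_sum_exact_oracle(x, y), rel=1e-9)


class TestCompareFeature:
    def test_group_contrast_on_synthetic_cohort(self, small_cohort):
        rows = []
        for taxon, models in small_cohort.annotations.items():
            rows.extend(feature_table(models, small_cohort.genomes[taxon]))
        comps = compare_feature(small_cohort.groups, rows, "intron_length")
        ev_s1 = next(
            c for c in comps if {c.group_a, c.group_b} == {"Ev", "S1"}
        )
        assert ev_s1.p_value < 0.001  # planted 100 vs 40 bp means
        means = group_means(small_cohort.groups, rows, "intron_length")
        assert means["Ev"] > means["S1"]

    def test_unknown_feature_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="unknown feature"):
            compare_feature(small_cohort.groups, [], "nope")
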
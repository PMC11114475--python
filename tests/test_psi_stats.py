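import math

import numpy as np
import pytest

from symbiopsi.homology import SetAssignment
from symbiopsi.io_formats import GroupAssignment, OrthoGroupTable
from symbiopsi.psi_stats import (
    PsiRecord,
    StatConfig,
    compare_psi,
    compute_psi,
    summarize_directions,
)

from oracles import fisher_exact_oracle

GROUPS = GroupAssignment({"t1": "Ev", "t2": "Ev", "t3": "S1", "t4": "S1"})


def rec(set_id, group, n_pseudo, n_genes):
    return PsiRecord(set_id, group, n_pseudo, n_genes)


class TestComputePsi:
    def test_ratio(self):
        table = OrthoGroupTable(
            {"OG0": {"t1": ["a", "b", "c"], "t2": ["d", "e", "f"]}}
        )
        sa = SetAssignment(
            assigned={f"c{i}": "OG0" for i in range(3)},
            taxon_of={"c0": "t1", "c1": "t1", "c2": "t2"},
        )
        records = compute_psi(sa, table, GROUPS)
        ev = next(r for r in records if r.group == "Ev")
        assert (ev.n_pseudo, ev.n_genes) == (3, 6)
        assert ev.psi == 0.5

    def test_zero_pseudogenes(self):
        table = OrthoGroupTable({"OG0": {"t1": ["a", "b"], "t2": ["c", "d"]}})
        sa = SetAssignment(assigned={}, taxon_of={})
        ev = next(
            r for r in compute_psi(sa, table, GROUPS) if r.group == "Ev"
        )
        assert ev.psi == 0.0

    def test_no_genes_psi_undefined(self):
        table = OrthoGroupTable({"OG0": {"t3": ["a"], "t4": ["b"]}})
        sa = SetAssignment(
            assigned={"c0": "OG0", "c1": "OG0"},
            taxon_of={"c0": "t1", "c1": "t1"},
        )
        ev = next(r for r in compute_psi(sa, table, GROUPS) if r.group == "Ev")
        assert ev.n_pseudo == 2 and ev.n_genes == 0
        assert math.isnan(ev.psi)

    def test_unlabeled_taxon_is_error(self):
        table = OrthoGroupTable({"OG0": {"mystery": ["a"]}})
        sa = SetAssignment(assigned={}, taxon_of={})
        with pytest.raises(KeyError, match="mystery"):
            compute_psi(sa, table, GROUPS)


class TestComparePsi:
    def test_strong_contrast_significant_and_directional(self):
        """(50 pseudo, 10 genes) vs (5, 100): Psi 5.0 vs 0.05; p verified
        against exact hypergeometric enumeration."""
        records = [rec("OG0", "S1", 50, 10), rec("OG0", "Ev", 5, 100)]
        (c,) = compare_psi(records, "S1", "Ev")
        assert c.direction == "a_gt_b"
        p_oracle = fisher_exact_oracle(50, 10, 5, 100)
        assert c.p_value == pytest.approx(p_oracle, rel=1e-9)
        assert c.p_value < 1e-10

    def test_identical_counts_p_one_no_direction(self):
        records = [rec("OG0", "S1", 4, 8), rec("OG0", "Ev", 4, 8)]
        (c,) = compare_psi(records, "S1", "Ev")
        assert c.p_value == 1.0 and c.direction == "none"

    def test_equal_ratios_never_directional(self):
        records = [rec("OG0", "S1", 1, 2), rec("OG0", "Ev", 2, 4)]
        (c,) = compare_psi(records, "S1", "Ev", StatConfig(alpha=0.99))
        assert c.direction == "none"

    def test_undefined_side_skipped(self):
        records = [rec("OG0", "S1", 3, 5), rec("OG0", "Ev", 2, 0)]
        assert compare_psi(records, "S1", "Ev") == []

    def test_relabel_flips_direction_preserves_p(self):
        rng = np.random.default_rng(0)
        records = []
        for i in range(30):
            records.append(rec(f"OG{i}", "S1", int(rng.poisson(5)), 8))
            records.append(rec(f"OG{i}", "Ev", int(rng.poisson(1)), 8))
        fwd = compare_psi(records, "S1", "Ev")
        back = compare_psi(records, "Ev", "S1")
        flip = {"a_gt_b": "b_gt_a", "b_gt_a": "a_gt_b", "none": "none"}
        for f, b in zip(fwd, back):
            assert f.p_value == pytest.approx(b.p_value, rel=1e-12)
            assert flip[f.direction] == b.direction

    def test_merged_labels_equal_pooled_counts(self):
        """Testing against S1+S2 equals pooling the counts beforehand."""
        records = [
            rec("OG0", "Ev", 2, 6),
            rec("OG0", "S1", 5, 4),
            rec("OG0", "S2", 3, 4),
        ]
        (merged,) = compare_psi(records, "S1+S2", "Ev")
        pooled = [rec("OG0", "S", 8, 8), rec("OG0", "Ev", 2, 6)]
        (direct,) = compare_psi(pooled, "S", "Ev")
        assert merged.p_value == pytest.approx(direct.p_value, rel=1e-12)
        assert (merged.n_pseudo_a, merged.n_genes_a) == (8, 8)
        assert merged.direction == direct.direction

    def test_binomial_ratio_alternative(self):
        records = [rec("OG0", "S1", 12, 4), rec("OG0", "Ev", 1, 4)]
        (c,) = compare_psi(records, "S1", "Ev", StatConfig(test="binomial_ratio"))
        assert 0.0 <= c.p_value < 0.05
        assert c.direction == "a_gt_b"


class TestSummarize:
    def test_empty_input_all_zero(self):
        assert summarize_directions([]) == {}

    def test_counts_partition_tested_sets(self):
        rng = np.random.default_rng(1)
        records = []
        for i in range(40):
            records.append(rec(f"OG{i}", "S1", int(rng.poisson(3)), 6))
            records.append(rec(f"OG{i}", "Ev", int(rng.poisson(3)), 6))
        comps = compare_psi(records, "S1", "Ev")
        (tally,) = summarize_directions(comps).values()
        assert sum(tally.values()) == len(comps) == 40
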
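"""Gene-set thresholds, BH adjustment, TE-list merging, Venn partition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tespectra.gene_sets import (
    GeneGroupPartition,
    GeneSet,
    bh_adjust,
    cpm_prefilter,
    de_gene_set,
    merge_te_lists,
    splicing_gene_set,
    venn_partition,
)
from tespectra.io_formats import GeneStatRecord


def bh_oracle(p):
    """Brute-force step-up definition: q_i = min over j with p_j >= p_i of
    p_(j) * n / rank(j), capped at 1, returned in input order."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q_sorted = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q_sorted[rank - 1] = running
    out = [0.0] * n
    for rank, i in enumerate(order):
        out[i] = min(q_sorted[rank], 1.0)
    return out


class TestDeGeneSet:
    def _rec(self, gid, p, lfc):
        return GeneStatRecord(gid, adjusted_p=p, log2_fold_change=lfc)

    def test_threshold_examples(self):
        recs = [
            self._rec("in", 0.04, 1.5),
            self._rec("small_fc", 0.04, 0.5),
            self._rec("big_p", 0.06, 3.0),
            self._rec("down", 0.01, -2.0),
        ]
        members = de_gene_set(recs).members
        assert members == {"in", "down"}

    def test_boundary_inclusive_by_default_strict_with_flag(self):
        rec = [self._rec("edge", 0.01, 1.0)]  # exactly two-fold
        assert "edge" in de_gene_set(rec)
        assert "edge" not in de_gene_set(rec, fc_strict=True)

    def test_missing_values_excluded(self):
        recs = [GeneStatRecord("m", adjusted_p=0.01)]
        assert len(de_gene_set(recs)) == 0

    def test_nonpositive_thresholds_rejected(self):
        with pytest.raises(ValueError):
            de_gene_set([], adj_p_max=0)
        with pytest.raises(ValueError):
            de_gene_set([], min_fold_change=-1)

    @given(
        p=st.floats(0.001, 0.2),
        lfc=st.floats(-4, 4),
        relax_p=st.floats(0, 0.5),
        relax_fc=st.floats(0, 1.0),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_relaxing_thresholds_is_monotone(self, p, lfc, relax_p, relax_fc):
        recs = [GeneStatRecord("g", adjusted_p=p, log2_fold_change=lfc)]
        tight = de_gene_set(recs, adj_p_max=0.05, min_fold_change=2.0)
        loose = de_gene_set(recs, adj_p_max=0.05 + relax_p, min_fold_change=max(2.0 - relax_fc, 1e-6))
        assert tight.members <= loose.members


class TestCpmPrefilter:
    def test_cpm_formula(self):
        counts = pd.DataFrame({"lib1": [1, 0]}, index=["kept", "zero"])
        counts.loc["filler"] = 10**6 - 1
        kept = cpm_prefilter(counts)
        assert "kept" in kept and "zero" not in kept  # CPM 1.0 vs 0.0

    def test_below_threshold_everywhere_removed(self):
        # CPM 0.4 in both libraries
        counts = pd.DataFrame({"a": [4, 10**7 - 4], "b": [4, 10**7 - 4]},
                              index=["low", "rest"])
        assert "low" not in cpm_prefilter(counts)

    def test_zero_total_library_rejected(self):
        counts = pd.DataFrame({"a": [0, 0]}, index=["x", "y"])
        with pytest.raises(ValueError, match="zero total"):
            cpm_prefilter(counts)


class TestBhAdjust:
    def test_hand_computed_examples(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([0.5]) == [0.5]
        assert bh_adjust([1.0, 1.0]) == [1.0, 1.0]
        assert bh_adjust([]) == []

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @given(p=st.lists(st.floats(0, 1), min_size=1, max_size=10))
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_matches_brute_force_step_up(self, p):
        assert bh_adjust(p) == pytest.approx(bh_oracle(p))

    @given(p=st.lists(st.floats(0, 1), min_size=2, max_size=10))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_monotone_in_raw_p_order(self, p):
        q = bh_adjust(p)
        paired = sorted(zip(p, q))
        assert all(paired[i][1] <= paired[i + 1][1] + 1e-12 for i in range(len(paired) - 1))


class TestMergeTeLists:
    def test_union_within_condition(self):
        lists = {
            "s1": GeneSet("s1", {"gA", "gB"}),
            "s2": GeneSet("s2", {"gB", "gC"}),
            "s3": GeneSet("s3", {"gD"}),
        }
        merged = merge_te_lists(lists, {"s1": "FXD", "s2": "FXD", "s3": "healthy"})
        assert merged["FXD"].members == {"gA", "gB", "gC"}
        assert merged["healthy"].members == {"gD"}

    def test_unassigned_sample_rejected(self):
        with pytest.raises(ValueError, match="no assigned condition"):
            merge_te_lists({"s1": GeneSet("s1", {"g"})}, {})

    def test_empty_lists(self):
        assert merge_te_lists({}, {}) == {}


class TestVennPartition:
    def test_enumerated_example(self):
        part = venn_partition(
            GeneSet("A", {"g1", "g2", "g3"}),
            GeneSet("B", set()),
            GeneSet("de", {"g1"}),
            GeneSet("splicing", {"g2"}),
        )
        assert part.cells["A_only:de"] == {"g1"}
        assert part.cells["A_only:splicing"] == {"g2"}
        assert part.cells["A_only:neither"] == {"g3"}

    def test_de_precedence_and_overlap_cell(self):
        te = GeneSet("A", {"g"})
        de, sp = GeneSet("de", {"g"}), GeneSet("splicing", {"g"})
        default = venn_partition(te, GeneSet("B", set()), de, sp)
        assert default.cells == {"A_only:de": frozenset({"g"})}
        explicit = venn_partition(te, GeneSet("B", set()), de, sp, overlap_cell=True)
        assert explicit.cells == {"A_only:de+splicing": frozenset({"g"})}

    def test_empty_universe(self):
        part = venn_partition(GeneSet("A", set()), GeneSet("B", set()),
                              GeneSet("de", set()), GeneSet("sp", set()))
        assert part.universe == frozenset() and part.cells == {}

    def test_partition_invariants_enforced(self):
        with pytest.raises(ValueError):
            GeneGroupPartition(frozenset({"a"}), {"c1": frozenset({"a"}), "c2": frozenset({"a"})})
        with pytest.raises(ValueError):
            GeneGroupPartition(frozenset({"a", "b"}), {"c1": frozenset({"a"})})

    @given(data=st.data())
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_cells_disjoint_and_cover_universe(self, data):
        genes = [f"g{i}" for i in range(12)]
        subset = lambda: set(data.draw(st.lists(st.sampled_from(genes), max_size=12)))
        te_a, te_b, de, sp = subset(), subset(), subset(), subset()
        part = venn_partition(
            GeneSet("A", te_a), GeneSet("B", te_b), GeneSet("de", de), GeneSet("sp", sp)
        )
        union = set()
        for members in part.cells.values():
            assert not (union & members)
            union |= members
        assert union == te_a | te_b


class TestSplicingGeneSet:
    def test_flagged_genes_only(self):
        recs = [
            GeneStatRecord("y", splicing_changed=True),
            GeneStatRecord("n", splicing_changed=False),
        ]
        assert splicing_gene_set(recs).members == {"y"}
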
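"""Substitution spectra, ratio statistic, dinucleotide densities, matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import revcomp
from tespectra.composition import (
    AT_TO_CG_CLASSES,
    CG_TO_AT_CLASSES,
    SUBSTITUTION_CLASSES,
    aggregate_group_matrix,
    count_substitutions,
    dinucleotide_density,
    row_zscore,
    substitution_ratio,
)

seq_strategy = st.text(alphabet="ACGT", min_size=1, max_size=80)
cons_strategy = st.text(alphabet="ACGTN", min_size=1, max_size=80)


def oracle_counts(ref: str, cons: str):
    """Position-by-position hand oracle for the spectrum."""
    classes = {c: 0 for c in SUBSTITUTION_CLASSES}
    n_to_n = 0
    for r, c in zip(ref, cons):
        if c == "N":
            n_to_n += 1
        elif r != c:
            classes[f"{r}>{c}"] += 1
    return classes, n_to_n


class TestCountSubstitutions:
    def test_identity_gives_all_zero(self):
        spec = count_substitutions("ACGT", "ACGT")
        assert spec.total_substitutions == 0 and spec.total_per_kb == 0.0

    def test_hand_enumerated_four_position_example(self):
        spec = count_substitutions("ATCG", "GCAT")
        assert spec.count("A>G") == 1 and spec.count("T>C") == 1
        assert spec.count("C>A") == 1 and spec.count("G>T") == 1
        assert spec.at_to_cg == 2 and spec.cg_to_at == 2
        assert substitution_ratio(spec) == 1.0

    def test_per_kb_normalization(self):
        spec = count_substitutions("AAAA", "CCCC")
        assert spec.count("A>C") == 4
        assert spec.total_per_kb == pytest.approx(4 / (4 / 1000))  # 1000.0

    def test_n_counts_toward_total_but_no_class(self):
        spec = count_substitutions("ACGT", "NNGT")
        assert spec.n_to_N == 2
        assert spec.at_to_cg == 0 and spec.cg_to_at == 0
        assert spec.total_substitutions == 2

    def test_length_mismatch_and_bad_bases_rejected(self):
        with pytest.raises(ValueError, match="length"):
            count_substitutions("ACG", "AC")
        with pytest.raises(ValueError, match="reference"):
            count_substitutions("ACNG", "ACGG")

    def test_exhaustive_oracle_two_letter_alphabet(self):
        """All reference/consensus pairs of length <= 6 over {A, C} match
        the position-by-position oracle."""
        from itertools import product

        for n in range(1, 7):
            for ref_t in product("AC", repeat=n):
                for cons_t in product("AC", repeat=n):
                    ref, cons = "".join(ref_t), "".join(cons_t)
                    spec = count_substitutions(ref, cons)
                    classes, n_to_n = oracle_counts(ref, cons)
                    assert dict(spec.class_counts) == classes
                    assert spec.n_to_N == n_to_n

    @given(ref=seq_strategy, cons=cons_strategy)
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_conservation_of_mismatches(self, ref, cons):
        n = min(len(ref), len(cons))
        ref, cons = ref[:n], cons[:n]
        spec = count_substitutions(ref, cons)
        mismatches = sum(1 for r, c in zip(ref, cons) if r != c)
        assert spec.total_substitutions == mismatches

    @given(ref=seq_strategy, cons=cons_strategy)
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_complement_closure_of_class_sums(self, ref, cons):
        """Reverse-complementing both sequences leaves the class sums (and
        hence the ratio) unchanged: each class set is complement-closed."""
        n = min(len(ref), len(cons))
        ref, cons = ref[:n], cons[:n]
        fwd = count_substitutions(ref, cons)
        rev = count_substitutions(revcomp(ref), revcomp(cons))
        assert fwd.at_to_cg == rev.at_to_cg
        assert fwd.cg_to_at == rev.cg_to_at


class TestSubstitutionRatio:
    def test_examples(self):
        from tespectra.composition import SubstitutionSpectrum

        spec = SubstitutionSpectrum("g", 100, {"A>C": 2, "C>A": 1}, 0)
        assert substitution_ratio(spec) == 2.0
        zero = SubstitutionSpectrum("g", 100, {}, 0)
        assert substitution_ratio(zero) is None
        pseudo = SubstitutionSpectrum("g", 100, {"A>C": 3}, 0)
        assert substitution_ratio(pseudo) is None
        assert substitution_ratio(pseudo, pseudocount=1) == 4.0

    def test_class_membership_definitions(self):
        assert set(AT_TO_CG_CLASSES) == {"A>C", "A>G", "T>C", "T>G"}
        assert set(CG_TO_AT_CLASSES) == {"C>A", "C>T", "G>A", "G>T"}


class TestDinucleotideDensity:
    @pytest.mark.parametrize(
        "seq,pattern,count,per_kb",
        [
            ("CGCG", "CG", 2, 500.0),
            ("GGGG", "CG", 0, 0.0),
            ("CNGCG", "CG", 1, 200.0),  # windows containing N skipped
        ],
    )
    def test_examples(self, seq, pattern, count, per_kb):
        d = dinucleotide_density(seq, pattern)
        assert d.count == count
        assert d.per_kb == pytest.approx(per_kb)

    def test_short_sequence(self):
        assert dinucleotide_density("C", "CG").count == 0

    def test_n_windows_excluded_from_valid(self):
        d = dinucleotide_density("CNGCG", "CG")
        assert d.n_valid_windows == 2  # CN, NG invalid; GC, CG valid

    def test_bad_pattern_rejected(self):
        with pytest.raises(ValueError):
            dinucleotide_density("ACGT", "CGA")
        with pytest.raises(ValueError):
            dinucleotide_density("ACGT", "CN")

    @given(seq=st.text(alphabet="ACGTN", min_size=2, max_size=100))
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_palindrome_invariance_cg_gc(self, seq):
        """CG and GC are reverse-complement palindromes: their counts are
        invariant under reverse complement."""
        for pattern in ("CG", "GC"):
            assert (
                dinucleotide_density(seq, pattern).count
                == dinucleotide_density(revcomp(seq), pattern).count
            )

    @given(seq=st.text(alphabet="ACGT", min_size=2, max_size=60))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_self_concatenation_scale_property(self, seq):
        """Doubling a sequence leaves per-kb density unchanged up to the one
        junction window."""
        single = dinucleotide_density(seq, "CG")
        double = dinucleotide_density(seq + seq, "CG")
        junction = 1 if seq[-1] == "C" and seq[0] == "G" else 0
        assert double.count == 2 * single.count + junction


class TestAggregation:
    def _long(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "sample", "replicate", "value"])

    def test_replicate_mean(self):
        table = self._long(
            [("gA", "s1", r, v) for r, v in zip((1, 2, 3), (1.0, 2.0, 3.0))]
        )
        mat = aggregate_group_matrix(table, {"grp": {"gA"}})
        assert mat.values.loc["grp", "s1"] == pytest.approx(2.0)

    def test_mean_of_gene_ratios(self):
        table = self._long([("gA", "s1", 1, 1.0), ("gB", "s1", 1, 3.0)])
        mat = aggregate_group_matrix(table, {"grp": {"gA", "gB"}})
        assert mat.values.loc["grp", "s1"] == pytest.approx(2.0)

    def test_ratio_of_summed_counts(self):
        table = pd.DataFrame(
            {
                "gene_id": ["gA", "gB"],
                "sample": ["s1", "s1"],
                "replicate": [1, 1],
                "at_to_cg": [2, 0],
                "cg_to_at": [1, 3],
            }
        )
        mat = aggregate_group_matrix(table, {"grp": {"gA", "gB"}}, scheme="ratio_of_summed_counts")
        assert mat.values.loc["grp", "s1"] == pytest.approx(0.5)

    def test_undefined_ratios_excluded_then_cell_missing(self):
        table = self._long([("gA", "s1", 1, np.nan), ("gB", "s1", 1, 4.0)])
        mat = aggregate_group_matrix(table, {"grp": {"gA", "gB"}, "empty": {"gA"}})
        assert mat.values.loc["grp", "s1"] == pytest.approx(4.0)
        assert np.isnan(mat.values.loc["empty", "s1"])

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            aggregate_group_matrix(self._long([]), {"g": set()}, scheme="median")


class TestRowZscore:
    def test_basic_row(self):
        frame = pd.DataFrame([[1.0, 2.0, 3.0]], index=["r"], columns=list("abc"))
        z = row_zscore(frame)
        assert z.loc["r"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_degenerate_rows_become_missing(self):
        frame = pd.DataFrame(
            [[5.0, 5.0, 5.0], [1.0, np.nan, np.nan]], index=["flat", "single"], columns=list("abc")
        )
        z = row_zscore(frame)
        assert z.isna().all(axis=None)

    def test_zscore_rows_have_mean0_sd1(self, rng):
        frame = pd.DataFrame(rng.normal(size=(5, 6)))
        z = row_zscore(frame)
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)
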
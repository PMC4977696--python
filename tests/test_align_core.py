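import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clusterscope import align_core as ac
from clusterscope.align_core import (NtScoring, PairwiseAlignment,
                                     classify_columns, global_align_aa,
                                     global_align_nt, overlap_align,
                                     percent_identity)
from clusterscope.formats_io import SeqRecord
from clusterscope.synthetic_data import split_with_overlap

from conftest import classify_oracle, gotoh_score, random_dna, random_protein


def nt_rec(name, seq):
    return SeqRecord(name, seq)


def aa_rec(name, seq):
    return SeqRecord(name, seq, alphabet="protein")


class TestGlobalAlignNt:
    def test_identical_sequences(self, rng):
        seq = random_dna(rng, 100)
        aln = global_align_nt(nt_rec("a", seq), nt_rec("b", seq))
        assert aln.score == 200.0
        counts = classify_columns(aln)
        assert counts.match == 100
        assert counts.genuine_substitution == counts.gap == 0

    def test_single_substitution(self):
        aln = global_align_nt(nt_rec("a", "ACGT"), nt_rec("b", "ACGA"))
        counts = classify_columns(aln)
        assert (counts.match, counts.genuine_substitution) == (3, 1)

    def test_protein_input_rejected(self):
        with pytest.raises(ValueError, match="nucleotide"):
            global_align_nt(aa_rec("p", "MK"), aa_rec("q", "ML"))

    @pytest.mark.parametrize("scoring", [
        NtScoring(), NtScoring(2, -3, -5, -2), NtScoring(1, -1, -2, -1)])
    def test_matches_full_dp_oracle(self, rng, scoring):
        def sub(x, y):
            return scoring.match if x == y else scoring.mismatch
        for _ in range(25):
            a = random_dna(rng, int(rng.integers(5, 51)))
            b = random_dna(rng, int(rng.integers(5, 51)))
            aln = global_align_nt(nt_rec("a", a), nt_rec("b", b), scoring)
            expected = gotoh_score(a, b, sub, scoring.gap_open, scoring.gap_extend)
            assert aln.score == pytest.approx(expected, abs=1e-9)

    def test_anchored_path_consistent_with_direct(self, rng, monkeypatch):
        seq = random_dna(rng, 2000)
        mutated = list(seq)
        for pos in rng.choice(2000, 100, replace=False):
            mutated[pos] = "ACGT".replace(seq[pos], "")[rng.integers(0, 3)]
        a, b = nt_rec("a", seq), nt_rec("b", "".join(mutated))
        direct = global_align_nt(a, b)
        monkeypatch.setattr(ac, "MAX_DP_CELLS", 40_000)
        anchored = global_align_nt(a, b)
        assert anchored.a_gapped.replace("-", "") == seq
        assert anchored.b_gapped.replace("-", "") == b.residues
        # anchored identity may differ from optimal only marginally
        assert percent_identity(anchored) == pytest.approx(
            percent_identity(direct), abs=0.005)


class TestGlobalAlignAa:
    def test_identical_proteins(self, rng):
        seq = random_protein(rng, 20)
        aln = global_align_aa(aa_rec("p", seq), aa_rec("q", seq))
        assert percent_identity(aln, "exclude_gap_columns") == 1.0

    def test_single_residue_difference(self):
        aln = global_align_aa(aa_rec("p", "MK"), aa_rec("q", "ML"))
        assert aln.a_gapped == "MK"
        assert aln.b_gapped == "ML"

    def test_nucleotide_input_rejected(self):
        with pytest.raises(ValueError, match="protein"):
            global_align_aa(nt_rec("a", "ACGT"), nt_rec("b", "ACGT"))

    def test_matches_full_dp_oracle(self, rng):
        from Bio.Align import substitution_matrices
        matrix = substitution_matrices.load("BLOSUM62")

        def sub(x, y):
            return matrix[x, y]
        for _ in range(25):
            a = random_protein(rng, int(rng.integers(5, 31)))
            b = random_protein(rng, int(rng.integers(5, 31)))
            aln = global_align_aa(aa_rec("p", a), aa_rec("q", b))
            assert aln.score == pytest.approx(gotoh_score(a, b, sub, -11, -1),
                                              abs=1e-9)


class TestOverlapAlign:
    def test_exact_shared_suffix_prefix(self):
        aln = overlap_align(nt_rec("a", "AAAACGTG"), nt_rec("b", "ACGTGTTT"))
        assert aln.a_gapped == "ACGTG"
        assert percent_identity(aln) == 1.0
        assert (aln.a_start, aln.a_end) == (3, 8)
        assert (aln.b_start, aln.b_end) == (0, 5)

    def test_planted_overlap_recovered(self, rng):
        record = SeqRecord("x", random_dna(rng, 8000))
        left, right, truth = split_with_overlap(record, 4000, overlap_len=400,
                                                overlap_divergence=0.04, seed=5)
        aln = overlap_align(left, right)
        assert abs(len(aln) - 400) <= 10
        assert percent_identity(aln) == pytest.approx(
            truth.realized_overlap_identity, abs=0.02)

    def test_random_pairs_give_weak_overlaps(self, rng):
        # empirical null: unrelated sequences never reach a long high-identity
        # overlap, which is what the downstream threshold filter relies on
        for _ in range(50):
            a = nt_rec("a", random_dna(rng, 600))
            b = nt_rec("b", random_dna(rng, 600))
            aln = overlap_align(a, b)
            assert len(aln) < 100 or percent_identity(aln) < 0.90

    def test_coordinates_reproduce_spans(self, rng):
        record = SeqRecord("x", random_dna(rng, 3000))
        left, right, _ = split_with_overlap(record, 1500, 200, 0.02, seed=9)
        aln = overlap_align(left, right)
        assert aln.a_gapped.replace("-", "") == \
            left.residues[aln.a_start:aln.a_end]
        assert aln.b_gapped.replace("-", "") == \
            right.residues[aln.b_start:aln.b_end]


def make_alignment(a_row, b_row, alphabet="nucleotide"):
    return PairwiseAlignment("a", "b", a_row, b_row, 0.0,
                             0, len(a_row) - a_row.count("-"),
                             0, len(b_row) - b_row.count("-"), alphabet)


class TestPercentIdentity:
    def test_identical_sequences_all_policies(self):
        aln = make_alignment("ACGTACGT", "ACGTACGT")
        for policy in ac.IDENTITY_POLICIES:
            assert percent_identity(aln, policy) == 1.0

    def test_forced_arithmetic(self):
        # 10 columns: 7 matches, 2 one-sided gaps, 1 substitution
        aln = make_alignment("ACGTACGTAC", "ACGTACG--A")
        assert percent_identity(aln, "all_columns") == pytest.approx(0.70)
        assert percent_identity(aln, "exclude_gap_columns") == pytest.approx(0.875)

    def test_only_genuine_substitutions_count_in_strictest_policy(self):
        # mirrors the published "99.99 %" framing: gaps and compatible
        # ambiguities are not genuine differences
        row_a = "A" * 53894 + "CCC" + "AAA"
        row_b = "A" * 53894 + "GGG" + "--A"
        row_b = row_b[:-1] + "R"
        aln = make_alignment(row_a, row_b)
        value = percent_identity(aln, "exclude_gap_and_ambiguity")
        assert value == pytest.approx(1.0 - 3 / 53900, abs=1e-9)

    def test_row_swap_invariance(self, rng):
        for _ in range(10):
            n = int(rng.integers(20, 200))
            a = random_dna(rng, n)
            b = random_dna(rng, n)
            aln = global_align_nt(nt_rec("a", a), nt_rec("b", b))
            for policy in ac.IDENTITY_POLICIES:
                assert percent_identity(aln, policy) == \
                    pytest.approx(percent_identity(aln.swapped(), policy))

    def test_empty_alignment_errors(self):
        aln = PairwiseAlignment("a", "b", "", "", 0.0)
        with pytest.raises(ValueError):
            percent_identity(aln)

    def test_unknown_policy_errors(self):
        with pytest.raises(ValueError, match="policy"):
            percent_identity(make_alignment("A", "A"), "bogus")


class TestClassifyColumns:
    def test_match_column(self):
        counts = classify_columns(make_alignment("A", "A"))
        assert counts.match == 1

    def test_compatible_ambiguity(self):
        counts = classify_columns(make_alignment("R", "A"))
        assert counts.ambiguity == 1

    def test_incompatible_ambiguity_is_substitution(self):
        counts = classify_columns(make_alignment("R", "C"))
        assert counts.genuine_substitution == 1

    def test_ambiguity_vs_itself_is_ambiguity(self):
        counts = classify_columns(make_alignment("R", "R"))
        assert counts.ambiguity == 1

    def test_non_iupac_character_names_column(self):
        aln = PairwiseAlignment("a", "b", "AXG", "AAG", 0.0, 0, 3, 0, 3)
        with pytest.raises(ValueError, match="column 1"):
            classify_columns(aln)

    def test_gap_only_column_rejected_at_construction(self):
        with pytest.raises(ValueError, match="gap-only"):
            PairwiseAlignment("a", "b", "A-G", "A-G", 0.0)

    def test_counts_match_brute_force_oracle(self, rng):
        from clusterscope.synthetic_data import plant_alignment
        for seed in range(5):
            aln, _ = plant_alignment(length=1000, n_subs=5, n_gap_cols=20,
                                     n_ambig=8, seed=seed)
            counts = classify_columns(aln)
            oracle = classify_oracle(aln.a_gapped, aln.b_gapped)
            assert counts.match == oracle["match"]
            assert counts.genuine_substitution == oracle["genuine_substitution"]
            assert counts.gap == oracle["gap"]
            assert counts.ambiguity == oracle["ambiguity"]

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_counts_sum_to_length(self, seed):
        rng = np.random.default_rng(seed)
        a = random_dna(rng, int(rng.integers(10, 120)))
        b = random_dna(rng, int(rng.integers(10, 120)))
        aln = global_align_nt(nt_rec("a", a), nt_rec("b", b))
        assert classify_columns(aln).total == len(aln)
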
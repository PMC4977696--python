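import numpy as np
import pytest

from clusterscope.align_core import PairwiseAlignment, global_align_nt
from clusterscope.cluster_profile import (Window, WindowIdentityProfile,
                                          conserved_group_differences,
                                          count_genuine_inconsistencies,
                                          detect_core_boundaries, marker_diff,
                                          star_align, window_identity_profile)
from clusterscope.formats_io import SeqRecord
from clusterscope.synthetic_data import plant_alignment, plant_events

from conftest import random_dna


def make_alignment(a_row, b_row):
    return PairwiseAlignment("a", "b", a_row, b_row, 0.0,
                             0, len(a_row) - a_row.count("-"),
                             0, len(b_row) - b_row.count("-"))


class TestWindowProfile:
    def test_identical_500_columns(self, rng):
        seq = random_dna(rng, 500)
        profile = window_identity_profile(make_alignment(seq, seq), 50)
        assert len(profile) == 10
        assert all(w.identity == 1.0 and w.cls == "full" for w in profile.windows)

    def test_short_trailing_remainder_merged(self, rng):
        seq = random_dna(rng, 520)
        profile = window_identity_profile(make_alignment(seq, seq), 50)
        assert len(profile) == 10
        assert profile.windows[-1].col_end - profile.windows[-1].col_start == 70

    def test_long_trailing_remainder_kept(self, rng):
        seq = random_dna(rng, 530)
        profile = window_identity_profile(make_alignment(seq, seq), 50)
        assert len(profile) == 11
        assert profile.windows[-1].col_end - profile.windows[-1].col_start == 30

    def test_alignment_shorter_than_window_is_single_window(self, rng):
        seq = random_dna(rng, 20)
        profile = window_identity_profile(make_alignment(seq, seq), 50)
        assert len(profile) == 1

    def test_windows_tile_without_overlap(self, rng):
        seq = random_dna(rng, 777)
        profile = window_identity_profile(make_alignment(seq, seq), 50)
        edges = [(w.col_start, w.col_end) for w in profile.windows]
        assert edges[0][0] == 0 and edges[-1][1] == 777
        for (_, e), (s, _) in zip(edges, edges[1:]):
            assert e == s

    def test_window_identities_match_direct_recomputation(self):
        aln, _ = plant_alignment(length=2000, n_subs=30, n_gap_cols=20,
                                 n_ambig=10, seed=4)
        profile = window_identity_profile(aln, 50)
        for w in profile.windows:
            matches = sum(1 for x, y in zip(aln.a_gapped[w.col_start:w.col_end],
                                            aln.b_gapped[w.col_start:w.col_end])
                          if x == y and x != "-" and x in "ACGT")
            assert w.identity == pytest.approx(matches / (w.col_end - w.col_start))

    def test_class_thresholds(self):
        # 10 matches -> full; 5/10 -> partial; 2/10 -> low
        aln = make_alignment("ACGTACGTAC" * 3,
                             "ACGTACGTAC" + "ACGTATTTTT" + "GTATTTTTGG")
        profile = window_identity_profile(aln, 10)
        assert [w.cls for w in profile.windows] == ["full", "partial", "low"]

    def test_small_window_rejected(self):
        with pytest.raises(ValueError, match="window_size"):
            window_identity_profile(make_alignment("ACGT", "ACGT"), 5)


def profile_from_identities(identities, w=50):
    """Build a profile (and consistent column matches) by hand."""
    windows = []
    matches = []
    for k, ident in enumerate(identities):
        cls = "full" if ident == 1.0 else ("low" if ident < 0.30 else "partial")
        windows.append(Window(k * w, (k + 1) * w, ident, cls))
        n_match = round(ident * w)
        matches.extend([1.0] * n_match + [0.0] * (w - n_match))
    return WindowIdentityProfile(w, windows, np.array(matches))


class TestDetectCoreBoundaries:
    def test_simple_island(self):
        profile = profile_from_identities([0.3, 0.3, 0.9, 0.9, 0.9, 0.3])
        core = detect_core_boundaries(profile)
        assert (core.window_start, core.window_end) == (2, 4)

    def test_everything_high_spans_whole_alignment(self):
        profile = profile_from_identities([0.95] * 8)
        core = detect_core_boundaries(profile)
        assert (core.window_start, core.window_end) == (0, 7)
        assert core.col_start == 0
        assert core.col_end == profile.n_columns

    def test_interior_dips_tolerated_up_to_max_low_run(self):
        profile = profile_from_identities(
            [0.2, 0.9, 0.9, 0.5, 0.5, 0.9, 0.9, 0.2])
        core = detect_core_boundaries(profile, max_low_run=2)
        assert (core.window_start, core.window_end) == (1, 6)

    def test_long_dip_splits_the_run(self):
        profile = profile_from_identities(
            [0.9, 0.9, 0.5, 0.5, 0.5, 0.9, 0.9, 0.9])
        core = detect_core_boundaries(profile, max_low_run=2)
        assert (core.window_start, core.window_end) == (5, 7)

    def test_sub_t_low_window_always_breaks(self):
        profile = profile_from_identities([0.9, 0.9, 0.2, 0.9, 0.9, 0.9])
        core = detect_core_boundaries(profile)
        assert (core.window_start, core.window_end) == (3, 5)

    def test_no_core_raises(self):
        profile = profile_from_identities([0.3, 0.4, 0.35])
        with pytest.raises(ValueError, match="no core"):
            detect_core_boundaries(profile)

    def test_core_identity_exceeds_flank_identity(self):
        profile = profile_from_identities([0.3, 0.9, 0.9, 0.3])
        core = detect_core_boundaries(profile)
        assert core.mean_core_identity > core.mean_flank_identity

    def test_mirror_symmetry(self, rng):
        # reversing the alignment mirrors the recovered boundaries
        identities = [0.31, 0.29, 0.88, 0.92, 0.95, 0.90, 0.33, 0.28]
        profile = profile_from_identities(identities)
        fwd = detect_core_boundaries(profile)
        rev_profile = profile_from_identities(identities[::-1])
        rev = detect_core_boundaries(rev_profile)
        n = profile.n_columns
        assert rev.col_start == n - fwd.col_end
        assert rev.col_end == n - fwd.col_start


class TestGenuineInconsistencies:
    def test_identical_sequences_zero(self, rng):
        seq = random_dna(rng, 300)
        assert count_genuine_inconsistencies(make_alignment(seq, seq))["count"] == 0

    def test_gap_column_not_counted(self):
        result = count_genuine_inconsistencies(make_alignment("ACGT", "A-GA"))
        assert result["count"] == 1
        assert result["positions"] == [3]

    def test_planted_alignment_exact_positions(self):
        aln, truth = plant_alignment(length=5000, n_subs=3, n_gap_cols=40,
                                     n_ambig=12, seed=11)
        result = count_genuine_inconsistencies(aln)
        assert result["count"] == 3
        assert result["positions"] == truth.substitution_positions

    def test_positions_ascending(self):
        aln, _ = plant_alignment(length=3000, n_subs=10, n_gap_cols=5,
                                 n_ambig=3, seed=2)
        positions = count_genuine_inconsistencies(aln)["positions"]
        assert positions == sorted(positions)


class TestMarkerDiff:
    def test_identical_markers(self, rng):
        seq = random_dna(rng, 600)
        counts = marker_diff(SeqRecord("a", seq), SeqRecord("b", seq))
        assert counts.genuine_substitution == 0

    def test_two_planted_substitutions(self, rng):
        marker = SeqRecord("its_a", random_dna(rng, 600))
        child, truth = plant_events(marker, n_subs=2, deletion_lengths=(),
                                    insertion_lengths=(), n_ambig=0,
                                    min_separation=50, seed=3, name="its_b")
        counts = marker_diff(marker, child)
        assert counts.genuine_substitution == len(truth.substitution_positions) == 2

    def test_substitution_and_indel_classes_separate(self, rng):
        marker = SeqRecord("cal_a", random_dna(rng, 700))
        child, _ = plant_events(marker, n_subs=1, deletion_lengths=(3,),
                                insertion_lengths=(), n_ambig=0,
                                min_separation=60, seed=8, name="cal_b")
        counts = marker_diff(marker, child)
        assert counts.genuine_substitution == 1
        assert counts.gap == 3


class TestConservedGroupDifferences:
    def test_single_diagnostic_column(self):
        rows = {"a1": "ACGT", "a2": "ACGT", "b1": "ACGA", "b2": "ACGA"}
        result = conserved_group_differences(rows, {"a1", "a2"}, {"b1", "b2"})
        assert result["count"] == 1
        assert result["columns"] == [3]

    def test_polymorphic_group_not_counted(self):
        rows = {"a1": "ACGT", "a2": "ACGC", "b1": "ACGA", "b2": "ACGA"}
        assert conserved_group_differences(rows, {"a1", "a2"},
                                           {"b1", "b2"})["count"] == 0

    def test_gap_and_ambiguity_columns_not_counted(self):
        rows = {"a1": "A-RT", "a2": "ACGT", "b1": "GCGA", "b2": "GCGA"}
        result = conserved_group_differences(rows, {"a1", "a2"}, {"b1", "b2"})
        # the gap column (1) and ambiguity column (2) are excluded
        assert result["columns"] == [0, 3]
        assert result["count"] == 2

    def test_row_length_mismatch_errors(self):
        rows = {"a1": "ACGT", "b1": "ACG"}
        with pytest.raises(ValueError, match="length"):
            conserved_group_differences(rows, {"a1"}, {"b1"})

    def test_overlapping_groups_rejected(self):
        rows = {"a1": "ACGT", "b1": "ACGT"}
        with pytest.raises(ValueError, match="disjoint"):
            conserved_group_differences(rows, {"a1"}, {"a1", "b1"})

    def test_brute_force_agreement_on_fixture(self):
        from clusterscope.synthetic_data import make_comparison_fixture
        bundle = make_comparison_fixture("two_clade_msa", seed=5)
        rows = bundle.rows
        ga = set(bundle.truth["group_a"])
        gb = set(bundle.truth["group_b"])
        result = conserved_group_differences(rows, ga, gb)

        def naive():
            cols = []
            n = len(next(iter(rows.values())))
            for c in range(n):
                xa = {rows[r][c] for r in ga}
                xb = {rows[r][c] for r in gb}
                if (len(xa) == 1 and len(xb) == 1 and xa <= set("ACGT")
                        and xb <= set("ACGT") and xa != xb):
                    cols.append(c)
            return cols
        assert result["columns"] == naive()


class TestStarAlign:
    def test_rows_equal_length_and_reproduce_inputs(self, rng):
        base = random_dna(rng, 300)
        records = [SeqRecord("r1", base),
                   SeqRecord("r2", base[:140] + base[160:]),
                   SeqRecord("r3", base[:200] + "ACGTA" + base[200:])]
        rows = star_align(records)
        lengths = {len(v) for v in rows.values()}
        assert len(lengths) == 1
        for rec in records:
            assert rows[rec.id].replace("-", "") == rec.residues

    def test_requires_two_records(self, rng):
        with pytest.raises(ValueError):
            star_align([SeqRecord("r1", random_dna(rng, 50))])
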
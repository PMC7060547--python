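"""Distance construction: cophenetic, homolog selection, masking, PIM."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylopep.distances import (
    DistanceMatrix, HomologHit, Supervector, conservation_mask,
    cophenetic_distances, dedup_identical_cog_sets, exclude_high_missing,
    percent_identity, pim_to_distances, read_homology_hits,
    select_cog_sequences, union_masks, validate_hit,
)


class TestDistanceMatrix:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0.5, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "A"], np.zeros((2, 2)))

    def test_long_tsv_roundtrip(self, tmp_path):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, .1, .2], [.1, 0, .3], [.2, .3, 0]]))
        path = tmp_path / "d.tsv"
        dm.write_tsv(path)
        back = DistanceMatrix.read_long_tsv(path)
        assert back.taxa == dm.taxa
        np.testing.assert_allclose(back.d, dm.d)

    def test_normalized(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0.0, 4.0], [4.0, 0.0]]))
        assert dm.normalized().get("A", "B") == 1.0


class TestCophenetic:
    def test_hand_path_sums(self):
        dm = cophenetic_distances("((A:1,B:1):1,C:2);")
        assert dm.get("A", "B") == pytest.approx(2.0)
        assert dm.get("A", "C") == pytest.approx(4.0)
        assert dm.get("B", "C") == pytest.approx(4.0)

    def test_single_leaf(self):
        dm = cophenetic_distances("A;")
        assert dm.taxa == ["A"] and dm.d.shape == (1, 1)

    def test_star_tree(self):
        dm = cophenetic_distances("(A:0.5,B:0.5,C:0.5);")
        for a, b in [("A", "B"), ("A", "C"), ("B", "C")]:
            assert dm.get(a, b) == pytest.approx(1.0)

    def test_missing_branch_length_rejected(self):
        with pytest.raises(ValueError, match="branch length"):
            cophenetic_distances("((A:1,B):1,C:2);")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(Exception):
            cophenetic_distances("((A:1,A:1):1,C:2);")

    def test_four_point_additivity_on_three_leaves(self):
        # any three leaves of an additive tree satisfy d(A,B) <= d(A,C)+d(B,C)
        dm = cophenetic_distances("((A:1,B:1):1,C:2);")
        t = dm.taxa
        for i in range(3):
            a, b, c = t[i], t[(i + 1) % 3], t[(i + 2) % 3]
            assert dm.get(a, b) <= dm.get(a, c) + dm.get(b, c) + 1e-12


class TestHomologValidation:
    @pytest.mark.parametrize("evalue, identity, coverage, ok", [
        (1e-5, 60.0, 0.95, True),
        (1e-5, 45.0, 0.95, False),   # identity strictly above 45
        (0.001, 60.0, 0.95, False),  # e-value strictly below 0.001
        (1e-5, 60.0, 0.94, False),   # coverage strictly above 0.94
        (0.0009999, 45.01, 0.9401, True),
    ])
    def test_strict_thresholds(self, evalue, identity, coverage, ok):
        hit = HomologHit("COG0012", "acc", evalue, identity, coverage)
        assert validate_hit(hit) is ok

    def test_tabular_parsing_with_coverage_column(self):
        text = ("COG0012\tWP_1\t60.0\t100\t5\t0\t1\t100\t1\t100\t1e-20\t"
                "200\t0.97\n")
        hits = read_homology_hits(text)
        assert validate_hit(hits["COG0012"][0])

    def test_coverage_from_query_length(self):
        text = "COG0012\tWP_1\t60.0\t95\t5\t0\t1\t95\t1\t95\t1e-20\t200\n"
        hits = read_homology_hits(text, query_lengths={"COG0012": 100})
        assert hits["COG0012"][0].coverage == pytest.approx(0.95)


class TestCogSelection:
    REF = Supervector("ref", {"COG0012": "MREF", "COG0016": "KREF"})

    def test_all_valid_no_missing(self):
        hits = {"COG0012": [HomologHit("COG0012", "s1", 1e-9, 60, 0.99)],
                "COG0016": [HomologHit("COG0016", "s2", 1e-9, 60, 0.99)]}
        seqs = {"s1": "MAAA", "s2": "KAAA"}
        chosen, missing = select_cog_sequences(
            7, ["COG0012", "COG0016"], hits, seqs, self.REF)
        assert missing == frozenset()
        assert chosen == {"COG0012": "MAAA", "COG0016": "KAAA"}

    def test_missing_filled_from_reference(self):
        chosen, missing = select_cog_sequences(
            7, ["COG0012", "COG0016"], {}, {}, self.REF)
        assert missing == frozenset({"COG0012", "COG0016"})
        assert chosen["COG0012"] == "MREF"

    def test_evalue_tie_prefers_identity(self):
        hits = {"COG0012": [
            HomologHit("COG0012", "low", 1e-9, 50, 0.99),
            HomologHit("COG0012", "high", 1e-9, 60, 0.99),
        ]}
        chosen, _ = select_cog_sequences(
            7, ["COG0012"], hits, {"low": "L", "high": "H"}, self.REF)
        assert chosen["COG0012"] == "H"


class TestExclusionsAndDedup:
    @pytest.mark.parametrize("missing, kept", [(0, True), (10, True),
                                               (11, False)])
    def test_missing_cog_boundary(self, missing, kept):
        out = exclude_high_missing(["t"], {"t": missing})
        assert (out == ["t"]) is kept

    def test_all_excluded_warns(self):
        with pytest.warns(UserWarning):
            assert exclude_high_missing(["t"], {"t": 50}) == []

    def test_identical_sets_grouped(self):
        sets = {5: {"COG0012": "MA"}, 3: {"COG0012": "MA"},
                9: {"COG0012": "MX"}}
        reps, inherit = dedup_identical_cog_sets(sets)
        assert reps == [3, 9]
        assert inherit == {3: 3, 5: 3, 9: 9}

    def test_all_distinct_identity(self):
        sets = {1: {"c": "A"}, 2: {"c": "B"}}
        reps, inherit = dedup_identical_cog_sets(sets)
        assert reps == [1, 2] and inherit == {1: 1, 2: 2}


class TestConservationMask:
    def test_modal_majority_column(self):
        mask = conservation_mask(["AA", "AA", "AA", "CA"], min_block=1)
        assert mask[0]  # A,A,A,C: 3/4 > 0.5

    def test_exact_half_not_conserved(self):
        mask = conservation_mask(["AA", "AA", "CA", "CA"], min_block=1)
        assert not mask[0]  # 2/4 = 0.5, strict

    def test_long_run_splits_and_short_blocks_drop(self):
        # conserved col + 9 non-conserved + conserved col: the run splits the
        # region and both length-1 blocks are discarded
        aln = ["A" + "X" * 9 + "A", "A" + "Y" * 9 + "A"]
        mask = conservation_mask(aln)
        assert not mask.any()

    def test_short_run_kept_inside_block(self):
        aln = ["A" + "X" * 8 + "A", "A" + "Y" * 8 + "A"]
        mask = conservation_mask(aln)
        assert mask.all()

    def test_gaps_do_not_disqualify_alone(self):
        # 3 residues agree among 4 sequences, one gap: 3/4 > 0.5 conserved
        mask = conservation_mask(["AA", "AA", "AA", "-A"], min_block=1)
        assert mask[0]

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError):
            conservation_mask(["AA", "A"])

    def test_limiting_behaviour(self):
        aln = ["AC", "AC", "AC", "AX"]
        # near-1 fraction keeps only perfectly conserved columns
        strict = conservation_mask(aln, min_fraction=0.99, min_block=1)
        assert strict.tolist() == [True, False]
        # zero fraction with unlimited run keeps everything conserved-capable
        loose = conservation_mask(aln, min_fraction=0.0,
                                  max_nonconserved_run=10**6, min_block=1)
        assert loose.all()


class TestMaskUnion:
    def test_boolean_or(self):
        out = union_masks([np.array([1, 1, 0, 0], bool),
                           np.array([0, 1, 1, 0], bool)])
        assert out.tolist() == [True, True, True, False]

    def test_single_mask_identity(self):
        m = np.array([True, False])
        assert union_masks([m]).tolist() == m.tolist()

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            union_masks([np.zeros(3, bool), np.zeros(4, bool)])


class TestPercentIdentity:
    def test_hand_count(self):
        assert percent_identity("ACDEFG", "ACDEYG") == pytest.approx(
            100 * 5 / 6)

    def test_identical(self):
        assert percent_identity("ACDE", "ACDE") == 100.0

    def test_gap_columns_excluded(self):
        # comparable columns are 1 and 3 only; both identical
        assert percent_identity("A-CD", "AEC-") == 100.0

    def test_no_comparable_columns(self):
        assert percent_identity("--", "AA") == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            percent_identity("AA", "AAA")

    @given(st.text(alphabet="ACDG-", min_size=1, max_size=30).flatmap(
        lambda a: st.tuples(
            st.just(a), st.text(alphabet="ACDG-", min_size=len(a),
                                max_size=len(a)))))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_permutation_invariant(self, pair):
        a, b = pair
        assert percent_identity(a, b) == percent_identity(b, a)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(a))
        pa = "".join(a[i] for i in perm)
        pb = "".join(b[i] for i in perm)
        assert percent_identity(pa, pb) == pytest.approx(
            percent_identity(a, b))


class TestPim:
    def test_identical_supervectors(self):
        dm = pim_to_distances(["A", "B"], ["MKV", "MKV"])
        assert dm.get("A", "B") == 0.0

    def test_from_identity_example(self):
        dm = pim_to_distances(["A", "B"], ["ACDEFG", "ACDEYG"])
        assert dm.get("A", "B") == pytest.approx(1 - 5 / 6)

    def test_three_taxa_symmetric(self):
        dm = pim_to_distances(["A", "B", "C"], ["AAAA", "AAAC", "AACC"])
        assert dm.d.shape == (3, 3)
        np.testing.assert_allclose(dm.d, dm.d.T)
        np.testing.assert_allclose(np.diag(dm.d), 0)
        assert np.all((dm.d >= 0) & (dm.d <= 1))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pim_to_distances(["A", "B"], ["AA", "AAA"])
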
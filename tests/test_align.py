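import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import modumap as mm
from modumap.align import score_columns

from conftest import make_alignment, random_protein
from oracles import brute_force_local

protein = st.text(alphabet=mm.AMINO_ACIDS, min_size=1, max_size=8).map(
    lambda s: mm.ProteinSequence("h", s))


class TestLocalAlign:
    def test_self_alignment_is_diagonal_sum(self, local_params, blosum80):
        seq = mm.ProteinSequence("p", "YGGFM")
        aln = mm.local_align(seq, seq, local_params)
        assert aln.score == sum(blosum80.score(c, c) for c in "YGGFM")
        assert aln.columns == tuple(zip("YGGFM", "YGGFM"))
        assert aln.query_span == aln.target_span == (1, 5)

    def test_all_negative_scores_give_empty_alignment(self, local_params,
                                                      blosum80):
        assert blosum80.score("W", "P") < 0
        aln = mm.local_align(mm.ProteinSequence("a", "WW"),
                             mm.ProteinSequence("b", "PP"), local_params)
        assert aln.score == 0
        assert aln.columns == ()
        assert aln.query_span is None

    def test_agrees_with_chain_enumeration_oracle(self, local_params):
        """DP optimum equals exhaustive enumeration on short random pairs."""
        rng = np.random.default_rng(42)
        for _ in range(150):
            a = random_protein(rng, int(rng.integers(1, 9)), "a")
            b = random_protein(rng, int(rng.integers(1, 9)), "b")
            assert mm.local_align(a, b, local_params).score == \
                brute_force_local(a, b, local_params)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(a=protein, b=protein)
    def test_score_nonnegative_and_recomputable(self, a, b, local_params):
        aln = mm.local_align(a, b, local_params)
        assert aln.score >= 0
        assert score_columns(aln.columns, local_params, aln.mode) == aln.score

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=protein, b=protein)
    def test_swap_preserves_score(self, a, b, local_params):
        """Matrix and gap symmetry make the optimum direction-independent."""
        fwd = mm.local_align(a, b, local_params).score
        rev = mm.local_align(b, a, local_params).score
        assert fwd == rev

    def test_stored_score_validated_at_construction(self, local_params):
        with pytest.raises(ValueError, match="recomputed"):
            mm.PairwiseAlignment(
                query_id="q", target_id="t", columns=(("A", "A"),),
                score=999, mode=mm.Mode.LOCAL, query_span=(1, 1),
                target_span=(1, 1), params=local_params)

    def test_gap_vs_gap_column_rejected(self, local_params):
        with pytest.raises(ValueError, match="gap-vs-gap"):
            make_alignment([("A", "A"), ("-", "-")], local_params)


class TestSuboptimal:
    def test_k1_equals_local_align(self, local_params):
        rng = np.random.default_rng(7)
        a = random_protein(rng, 30, "a")
        b = random_protein(rng, 50, "b")
        best = mm.local_align(a, b, local_params)
        sub = mm.suboptimal_alignments(a, b, local_params, max_alignments=1)
        assert len(sub) == 1
        assert sub[0].columns == best.columns
        assert sub[0].score == best.score

    def test_duplicated_motif_found_twice_disjointly(self, local_params,
                                                     blosum80):
        a = mm.ProteinSequence("a", "YGGFMAAAAAYGGFM")
        b = mm.ProteinSequence("b", "YGGFM")
        alns = mm.suboptimal_alignments(a, b, local_params, min_score=20)
        assert len(alns) == 2
        motif_score = sum(blosum80.score(c, c) for c in "YGGFM")
        assert [x.score for x in alns] == [motif_score, motif_score]
        assert {x.query_span for x in alns} == {(1, 5), (11, 15)}
        assert not (alns[0].aligned_pairs & alns[1].aligned_pairs)

    def test_second_alignment_matches_masked_oracle(self, local_params):
        """Declumping equals brute force with the first pairs forbidden."""
        rng = np.random.default_rng(11)
        for _ in range(40):
            a = random_protein(rng, int(rng.integers(4, 9)), "a")
            b = random_protein(rng, int(rng.integers(4, 9)), "b")
            alns = mm.suboptimal_alignments(a, b, local_params,
                                            max_alignments=2)
            if not alns:
                continue
            forbidden = np.zeros((len(a), len(b)), dtype=bool)
            for qi, ti in alns[0].aligned_pairs:
                forbidden[qi, ti] = True
            expected = brute_force_local(a, b, local_params, forbidden)
            got = alns[1].score if len(alns) > 1 else 0
            assert got == expected

    def test_unrelated_sequences_no_hits_at_threshold(self, local_params):
        rng = np.random.default_rng(3)
        a = random_protein(rng, 20, "a")
        b = random_protein(rng, 40, "b")
        assert mm.suboptimal_alignments(a, b, local_params,
                                        min_score=35) == []

    def test_declumping_invariants(self, local_params):
        """Non-increasing scores; pairwise-disjoint pairs; k=1 is a prefix."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = random_protein(rng, 40, "a")
            b = random_protein(rng, 40, "b")
            alns = mm.suboptimal_alignments(a, b, local_params,
                                            max_alignments=6)
            scores = [x.score for x in alns]
            assert scores == sorted(scores, reverse=True)
            seen = set()
            for x in alns:
                assert not (x.aligned_pairs & seen)
                seen |= x.aligned_pairs
            one = mm.suboptimal_alignments(a, b, local_params,
                                           max_alignments=1)
            if alns:
                assert one[0].columns == alns[0].columns

    def test_bad_max_alignments(self, local_params):
        a = mm.ProteinSequence("a", "YGGFM")
        with pytest.raises(ValueError):
            mm.suboptimal_alignments(a, a, local_params, max_alignments=0)


class TestGlobalFreeEnds:
    def test_self_alignment_all_identity(self, global_params, blosum80):
        rng = np.random.default_rng(9)
        for n in (5, 40, 120):
            a = random_protein(rng, n, "a")
            aln = mm.global_align_free_ends(a, a, global_params)
            assert aln.score == sum(blosum80.score(c, c) for c in a.residues)
            assert all(q == t for q, t in aln.columns)

    def test_contained_fragment_forced_by_free_ends(self, global_params,
                                                    blosum80):
        aln = mm.global_align_free_ends(mm.ProteinSequence("a", "YGGFM"),
                                        mm.ProteinSequence("b", "GGF"),
                                        global_params)
        assert aln.score == 2 * blosum80.score("G", "G") + blosum80.score("F", "F")
        # all residues of both sequences appear in the columns
        assert "".join(q for q, _ in aln.columns if q != "-") == "YGGFM"
        assert "".join(t for _, t in aln.columns if t != "-") == "GGF"
        assert aln.columns[1:4] == (("G", "G"), ("G", "G"), ("F", "F"))

    def test_every_residue_in_exactly_one_column(self, global_params):
        rng = np.random.default_rng(21)
        a = random_protein(rng, 37, "a")
        b = random_protein(rng, 61, "b")
        aln = mm.global_align_free_ends(a, b, global_params)
        assert "".join(q for q, _ in aln.columns if q != "-") == a.residues
        assert "".join(t for _, t in aln.columns if t != "-") == b.residues

    def test_agrees_with_independent_aligner(self, global_params):
        """Cross-check against biopython's free-end-gap global aligner."""
        from Bio import Align
        from Bio.Align import substitution_matrices
        arr = substitution_matrices.Array(alphabet=mm.ALPHABET, dims=2)
        for i, aa in enumerate(mm.ALPHABET):
            for j, bb in enumerate(mm.ALPHABET):
                arr[aa, bb] = global_params.matrix.scores[i, j]
        ref = Align.PairwiseAligner()
        ref.mode = "global"
        ref.substitution_matrix = arr
        ref.open_gap_score = global_params.gap_open
        ref.extend_gap_score = global_params.gap_extend
        ref.target_end_open_gap_score = 0
        ref.target_end_extend_gap_score = 0
        ref.query_end_open_gap_score = 0
        ref.query_end_extend_gap_score = 0
        rng = np.random.default_rng(13)
        for _ in range(40):
            a = random_protein(rng, int(rng.integers(1, 60)), "a")
            b = random_protein(rng, int(rng.integers(1, 60)), "b")
            mine = mm.global_align_free_ends(a, b, global_params).score
            assert mine == int(ref.score(a.residues, b.residues))


class TestClassifyColumns:
    def test_self_alignment_all_identity(self, local_params):
        seq = mm.ProteinSequence("p", "YGGFM")
        aln = mm.local_align(seq, seq, local_params)
        assert set(mm.classify_columns(aln)) == {mm.ColumnClass.IDENTITY}

    def test_positive_offdiagonal_is_similar(self, local_params, blosum80):
        assert blosum80.score("L", "I") > 0
        aln = make_alignment([("L", "I")], local_params)
        assert mm.classify_columns(aln) == [mm.ColumnClass.SIMILAR]

    def test_gap_and_dissimilar_and_x(self, local_params, blosum80):
        cols = [("A", "A"), ("A", "-"), ("W", "P"), ("X", "X")]
        aln = make_alignment(cols, local_params)
        assert mm.classify_columns(aln) == [
            mm.ColumnClass.IDENTITY, mm.ColumnClass.GAP,
            mm.ColumnClass.DISSIMILAR, mm.ColumnClass.DISSIMILAR]


class TestParams:
    def test_gap_ordering_enforced(self, blosum80):
        with pytest.raises(ValueError):
            mm.AlignmentParams(matrix=blosum80, gap_open=-2, gap_extend=-10)

    def test_mode_mismatch_rejected(self, local_params, global_params):
        a = mm.ProteinSequence("a", "YGGFM")
        with pytest.raises(ValueError):
            mm.local_align(a, a, global_params)
        with pytest.raises(ValueError):
            mm.global_align_free_ends(a, a, local_params)
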
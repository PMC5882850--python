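"""Pairwise and star alignment: oracle agreement, symmetry, coordinate maps."""

import itertools

import numpy as np
import pytest

from optoxr.align import (
    MultipleAlignment,
    SubstitutionMatrix,
    global_align,
    map_position,
    star_msa,
)
from optoxr.errors import BoundsError, ParameterError
from optoxr.fixtures import make_7tm, make_family
from optoxr.seqio import ProteinSequence

B62 = SubstitutionMatrix.blosum62()


def brute_force_score(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> int:
    """Independent oracle: enumerate every global alignment recursively.

    ``prev`` tracks whether the previous column opened a gap in the same row,
    so affine costs are charged exactly as gap_open + (L-1)*gap_extend.
    """

    def rec(i, j, prev):
        if i == len(a) and j == len(b):
            return 0
        best = -(10**9)
        if i < len(a) and j < len(b):
            best = max(best, matrix.score(a[i], b[j]) + rec(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if prev == "X" else gap_open
            best = max(best, -cost + rec(i + 1, j, "X"))
        if j < len(b):
            cost = gap_extend if prev == "Y" else gap_open
            best = max(best, -cost + rec(i, j + 1, "Y"))
        return best

    return rec(0, 0, None)


class TestGlobalAlign:
    def test_identity_blosum_diagonal(self):
        # A, C, D, E diagonal entries of BLOSUM62 are 4, 9, 6, 5
        aln = global_align(ProteinSequence("a", "ACDE"), ProteinSequence("b", "ACDE"), B62)
        assert aln.score == 24
        assert "-" not in aln.aligned_a + aln.aligned_b

    def test_short_vs_long_matches_bruteforce(self):
        a, b = "A", "AAAA"
        aln = global_align(ProteinSequence("a", a), ProteinSequence("b", b), B62, 10, 1)
        assert aln.score == brute_force_score(a, b, B62, 10, 1)

    @pytest.mark.parametrize("seq", ["MKT", "WWW", "ACDEFGHIK"])
    def test_self_alignment_is_gapless(self, seq):
        aln = global_align(ProteinSequence("a", seq), ProteinSequence("b", seq), B62)
        assert aln.score == sum(B62.score(c, c) for c in seq)
        assert aln.aligned_a == aln.aligned_b == seq

    def test_exhaustive_oracle_small(self):
        """DP equals enumeration for all pairs of length <= 2 over {A,C,D,E}."""
        alphabet = "ACDE"
        seqs = [
            "".join(t)
            for n in (1, 2)
            for t in itertools.product(alphabet, repeat=n)
        ]
        for sa in seqs:
            for sb in seqs:
                got = global_align(
                    ProteinSequence("a", sa), ProteinSequence("b", sb), B62, 10, 1
                ).score
                assert got == brute_force_score(sa, sb, B62, 10, 1), (sa, sb)

    def test_score_symmetry(self):
        rng = np.random.default_rng(42)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(50):
            a = "".join(rng.choice(letters, size=rng.integers(1, 30)))
            b = "".join(rng.choice(letters, size=rng.integers(1, 30)))
            sa = global_align(ProteinSequence("a", a), ProteinSequence("b", b), B62).score
            sb = global_align(ProteinSequence("b", b), ProteinSequence("a", a), B62).score
            assert sa == sb

    def test_gap_cost_arithmetic(self):
        """Inserting a run of length L costs gap_open + (L-1)*gap_extend."""
        x = "MKTAYIAKQR"
        base = global_align(ProteinSequence("a", x), ProteinSequence("b", x), B62, 10, 1).score
        for L in (1, 2, 3):
            y = x[:5] + "G" * L + x[5:]
            s = global_align(ProteinSequence("a", x), ProteinSequence("b", y), B62, 10, 1).score
            assert s == base - (10 + (L - 1) * 1)

    def test_emitted_alignment_rescoring_matches(self):
        rng = np.random.default_rng(7)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            a = "".join(rng.choice(letters, size=rng.integers(3, 40)))
            b = "".join(rng.choice(letters, size=rng.integers(3, 40)))
            aln = global_align(ProteinSequence("a", a), ProteinSequence("b", b), B62, 10, 1)
            assert aln.recompute_score(B62, 10, 1) == aln.score

    def test_scores_match_independent_aligner(self):
        """Cross-check scores against Biopython's PairwiseAligner."""
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = __import__(
            "Bio.Align.substitution_matrices", fromlist=["load"]
        ).load("BLOSUM62")
        aligner.open_gap_score = -10
        aligner.extend_gap_score = -1
        rng = np.random.default_rng(3)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            a = "".join(rng.choice(letters, size=rng.integers(2, 35)))
            b = "".join(rng.choice(letters, size=rng.integers(2, 35)))
            ours = global_align(ProteinSequence("a", a), ProteinSequence("b", b), B62, 10, 1).score
            assert ours == int(aligner.score(a, b))

    def test_empty_input_rejected(self):
        with pytest.raises((ParameterError, Exception)):
            global_align(ProteinSequence("a", "A"), ProteinSequence("b", ""), B62)


class TestStarMsa:
    def test_identical_family_has_no_gap_columns(self):
        ref = ProteinSequence("r", "MKTAYIAKQRQISFVK")
        msa = star_msa(ref, [ProteinSequence(f"h{i}", ref.residues) for i in range(5)])
        assert all("-" not in row for row in msa.rows)
        assert len(msa.rows) == 6

    def test_single_other_equals_pairwise(self):
        ref = ProteinSequence("r", "MKTAYIAKQR")
        other = ProteinSequence("o", "MKTAYIGGAKQR")
        aln = global_align(ref, other, B62)
        msa = star_msa(ref, [other])
        assert msa.rows[0] == aln.aligned_a
        assert msa.rows[1] == aln.aligned_b

    def test_substitution_only_family_stays_rectangular(self):
        truth = make_7tm(7, tm_len_range=(18, 22), loop_len_range=(10, 20))
        family = make_family(truth, n=6, sub_rate=0.05, seed=7)
        msa = star_msa(truth.protein, family)
        assert msa.n_columns == len(truth.protein)
        assert all("-" not in row for row in msa.rows)

    def test_empty_family_rejected(self):
        with pytest.raises(ParameterError):
            star_msa(ProteinSequence("r", "MKT"), [])


class TestMapPosition:
    def test_identity_is_identity(self):
        ref = ProteinSequence("r", "MKTAY")
        msa = star_msa(ref, [ProteinSequence("o", "MKTAY")])
        for k in range(5):
            assert map_position(msa, 1, k) == k

    def test_hand_built_leading_gap(self):
        # row 1 has one extra leading residue relative to the reference
        msa = MultipleAlignment(ids=("ref", "row"), rows=("-ACD", "WACD"))
        assert map_position(msa, 1, 0) is None  # W sits over a reference gap
        assert map_position(msa, 1, 1) == 0
        assert map_position(msa, 1, 3) == 2

    def test_row_starting_with_gap(self):
        msa = MultipleAlignment(ids=("ref", "row"), rows=("ACDE", "-CDE"))
        assert map_position(msa, 1, 0) == 1

    def test_out_of_range(self):
        msa = MultipleAlignment(ids=("ref", "row"), rows=("ACD", "ACD"))
        with pytest.raises(BoundsError):
            map_position(msa, 1, 9)
        with pytest.raises(BoundsError):
            map_position(msa, 5, 0)
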
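"""Pairwise/progressive alignment and percent identity.

The independent oracle for the Gotoh aligner is an exhaustive recursion
over every global alignment path (no dynamic programming), scoring affine
gaps by tracking only the preceding move.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alphafam.align import (
    GAP,
    Msa,
    PairwiseAlignment,
    ScoringScheme,
    global_align,
    identity_matrix,
    pair_from_msa,
    percent_identity,
    progressive_align,
    read_alignment,
    write_alignment,
)
from alphafam.seqio import AMINO_ACIDS, ProteinSequence


def brute_force_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Maximum global alignment score by exhaustive path enumeration."""
    go, ge = scheme.gap_open, scheme.gap_extend
    best = -np.inf

    def rec(i, j, last, score):
        nonlocal best
        if i == len(a) and j == len(b):
            if score > best:
                best = score
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + scheme.score(a[i], b[j]))
        if i < len(a):
            rec(i + 1, j, "X", score - (ge if last == "X" else go + ge))
        if j < len(b):
            rec(i, j + 1, "Y", score - (ge if last == "Y" else go + ge))

    rec(0, 0, None, 0.0)
    return best


def random_protein(rng, min_len=1, max_len=8) -> str:
    n = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


class TestGlobalAlign:
    def test_identical_sequences_align_gap_free(self):
        scheme = ScoringScheme()
        p = ProteinSequence(id="p", residues="MKVLAT")
        aln = global_align(p, ProteinSequence(id="q", residues="MKVLAT"), scheme)
        assert aln.a_aligned == aln.b_aligned == "MKVLAT"
        assert aln.score == pytest.approx(
            sum(scheme.score(c, c) for c in "MKVLAT")
        )

    def test_empty_sequence_rejected_at_construction(self):
        with pytest.raises(ValueError):
            ProteinSequence(id="e", residues="")

    def test_degapping_recovers_inputs(self, rng):
        scheme = ScoringScheme()
        for _ in range(25):
            a, b = random_protein(rng, 1, 12), random_protein(rng, 1, 12)
            aln = global_align(
                ProteinSequence(id="a", residues=a),
                ProteinSequence(id="b", residues=b),
                scheme,
            )
            assert aln.a_aligned.replace(GAP, "") == a
            assert aln.b_aligned.replace(GAP, "") == b

    def test_score_matches_exhaustive_enumeration(self, rng):
        scheme = ScoringScheme()
        for _ in range(60):
            a, b = random_protein(rng), random_protein(rng)
            aln = global_align(
                ProteinSequence(id="a", residues=a),
                ProteinSequence(id="b", residues=b),
                scheme,
            )
            assert aln.score == pytest.approx(brute_force_score(a, b, scheme))

    def test_alignment_score_consistent_with_emitted_columns(self, rng):
        # The reported score equals the score of the emitted alignment.
        scheme = ScoringScheme()
        for _ in range(20):
            a, b = random_protein(rng, 2, 10), random_protein(rng, 2, 10)
            aln = global_align(
                ProteinSequence(id="a", residues=a),
                ProteinSequence(id="b", residues=b),
                scheme,
            )
            score, in_gap = 0.0, None
            for x, y in zip(aln.a_aligned, aln.b_aligned):
                if x != GAP and y != GAP:
                    score += scheme.score(x, y)
                    in_gap = None
                else:
                    which = "a" if x == GAP else "b"
                    score -= scheme.gap_extend
                    if in_gap != which:
                        score -= scheme.gap_open
                    in_gap = which
            assert aln.score == pytest.approx(score)


class TestPercentIdentity:
    @pytest.mark.parametrize(
        "a, b, convention, expected",
        [
            ("AAAA", "AAAT", "aligned_columns", 75.0),
            ("AAAA", "AAAA", "aligned_columns", 100.0),
            ("AA--", "AAGG", "aligned_columns", 50.0),
            ("AA--", "AAGG", "ungapped_columns", 100.0),
            ("AA--", "AAGG", "shorter_seq", 100.0),
        ],
    )
    def test_conventions(self, a, b, convention, expected):
        aln = PairwiseAlignment(
            a_id="a", b_id="b", a_aligned=a, b_aligned=b, score=0.0
        )
        assert percent_identity(aln, convention) == pytest.approx(expected)

    def test_symmetry_in_rows(self, rng):
        for _ in range(20):
            a, b = random_protein(rng, 4, 10), random_protein(rng, 4, 10)
            aln = global_align(
                ProteinSequence(id="a", residues=a),
                ProteinSequence(id="b", residues=b),
            )
            swapped = PairwiseAlignment(
                a_id="b", b_id="a",
                a_aligned=aln.b_aligned, b_aligned=aln.a_aligned,
                score=aln.score,
            )
            for conv in ("aligned_columns", "shorter_seq", "ungapped_columns"):
                assert percent_identity(aln, conv) == pytest.approx(
                    percent_identity(swapped, conv)
                )

    @given(st.text(alphabet="ARNDC", min_size=1, max_size=8))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_invariant_under_appending_identical_columns(self, extra):
        base = PairwiseAlignment(
            a_id="a", b_id="b", a_aligned="MKVA", b_aligned="MRVA", score=0.0
        )
        grown = PairwiseAlignment(
            a_id="a", b_id="b",
            a_aligned="MKVA" + extra, b_aligned="MRVA" + extra, score=0.0,
        )
        before = percent_identity(base, "aligned_columns")
        after = percent_identity(grown, "aligned_columns")
        # appending identical columns can only raise identity toward 100
        assert after >= before


class TestMsa:
    def test_rejects_ragged_rows(self):
        with pytest.raises(ValueError):
            Msa(ids=["a", "b"], seqs=["MK", "MKV"])

    def test_rejects_all_gap_column(self):
        with pytest.raises(ValueError):
            Msa(ids=["a", "b"], seqs=["M-K", "M-V"])

    def test_coordinate_maps_round_trip(self):
        msa = Msa(ids=["a", "b"], seqs=["M-KV", "MAK-"])
        assert msa.column_of("a", 2) == 2  # K
        assert msa.position_at("a", 2) == 2
        assert msa.position_at("a", 1) is None
        assert msa.ungapped("b") == "MAK"
        for pos in range(1, 4):
            assert msa.position_at("b", msa.column_of("b", pos)) == pos

    def test_clustal_round_trip(self, tmp_path):
        msa = Msa(ids=["seq1", "seq2"], seqs=["MKV-AT", "MKVLAT"])
        path = tmp_path / "aln.aln"
        write_alignment(msa, path)
        back = read_alignment(path)
        assert back.ids == msa.ids and back.seqs == msa.seqs


class TestIdentityMatrix:
    def test_matches_pairwise_recomputation(self, rng):
        msa = Msa(
            ids=["a", "b", "c"],
            seqs=["MKV-ATGH", "MKVLATGH", "MRV-TTGH"],
        )
        mat = identity_matrix(msa)
        for i, x in enumerate(msa.ids):
            for j, y in enumerate(msa.ids):
                if i == j:
                    continue
                expected = percent_identity(pair_from_msa(msa, x, y))
                assert mat.values[i, j] == pytest.approx(expected)

    def test_duplicated_sequence_gives_all_100(self):
        msa = Msa(ids=["a", "b", "c"], seqs=["MKVL"] * 3)
        assert np.allclose(identity_matrix(msa).values, 100.0)

    def test_symmetric_with_diagonal_100(self, small_family):
        msa = progressive_align(small_family)
        mat = identity_matrix(msa)
        assert np.allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 100.0)


class TestProgressiveAlign:
    def test_two_sequences_reduce_to_pairwise(self):
        a = ProteinSequence(id="a", residues="MKVLAT")
        b = ProteinSequence(id="b", residues="MKLAT")
        msa = progressive_align([a, b])
        aln = global_align(a, b)
        assert msa.seqs == [aln.a_aligned, aln.b_aligned]

    def test_identical_sequences_give_gap_free_msa(self):
        seqs = [
            ProteinSequence(id=f"t{k}", residues="MKVLATGHEW") for k in range(6)
        ]
        msa = progressive_align(seqs)
        assert all(GAP not in s for s in msa.seqs)

    def test_row_order_follows_input_order(self, small_family):
        msa = progressive_align(small_family)
        assert msa.ids == [s.id for s in small_family]

    def test_degapping_recovers_each_input(self, small_family):
        msa = progressive_align(small_family)
        for seq in small_family:
            assert msa.ungapped(seq.id) == seq.residues

    def test_requires_two_sequences(self, small_family):
        with pytest.raises(ValueError):
            progressive_align(small_family[:1])
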
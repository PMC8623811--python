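"""Pairwise and progressive alignment against independent oracles."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chdcons import ProteinRecord, ScoringScheme, ValidationError
from chdcons.msa import (
    build_guide_tree,
    pairwise_align,
    pairwise_p_distance,
    progressive_align,
)
from chdcons.phylo import robinson_foulds
from chdcons.seqio import newick_string, tree_from_newick

from .oracles import (
    affine_optimum_enumerated,
    affine_optimum_recursive,
    sum_of_pairs_score,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
SCHEME = ScoringScheme()


def matrix_score(x: str, y: str) -> float:
    from chdcons.msa import _AA_INDEX

    return float(SCHEME.matrix[_AA_INDEX[x], _AA_INDEX[y]])


class TestPairwiseAlign:
    @pytest.mark.parametrize("a,b,expected", [
        ("MKL", "MKL", 14.0),   # B62 diagonal: M=5, K=5, L=4
        ("A", "A", 4.0),
    ])
    def test_identity_scores(self, a, b, expected):
        aln, score = pairwise_align(a, b)
        assert score == expected
        assert aln.seqs == [a, b]

    def test_single_gap_placed_optimally(self):
        aln, score = pairwise_align("ACDEF", "ACEF")
        assert aln.seqs == ["ACDEF", "AC-EF"]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_align("", "MKL")

    def test_matches_recursive_oracle_on_random_pairs(self):
        rng = random.Random(1234)
        for _ in range(60):
            a = "".join(rng.choices(AA, k=rng.randint(1, 8)))
            b = "".join(rng.choices(AA, k=rng.randint(1, 8)))
            _, score = pairwise_align(a, b)
            expect = affine_optimum_recursive(
                a, b, matrix_score, SCHEME.gap_open, SCHEME.gap_extend)
            assert score == pytest.approx(expect), (a, b)

    def test_matches_full_enumeration_on_tiny_pairs(self):
        rng = random.Random(99)
        for _ in range(12):
            a = "".join(rng.choices(AA, k=rng.randint(1, 4)))
            b = "".join(rng.choices(AA, k=rng.randint(1, 4)))
            _, score = pairwise_align(a, b)
            expect = affine_optimum_enumerated(
                a, b, matrix_score, SCHEME.gap_open, SCHEME.gap_extend)
            assert score == pytest.approx(expect), (a, b)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet=AA, min_size=1, max_size=12),
           st.text(alphabet=AA, min_size=1, max_size=12))
    def test_score_symmetric(self, a, b):
        _, s1 = pairwise_align(a, b)
        _, s2 = pairwise_align(b, a)
        assert s1 == pytest.approx(s2)

    def test_alignment_rows_ungap_to_inputs(self):
        aln, _ = pairwise_align("MKWVLDE", "MKVLE")
        assert aln.ungapped("a") == "MKWVLDE"
        assert aln.ungapped("b") == "MKVLE"


class TestGuideTree:
    def test_two_records_make_a_cherry(self):
        recs = [ProteinRecord("a", "F1", "s1", "MKL"),
                ProteinRecord("b", "F2", "s1", "MKV")]
        t = build_guide_tree(recs)
        assert {lf.taxon.label for lf in t.leaf_node_iter()} == {"a", "b"}

    def test_identical_pair_joined_first(self):
        recs = [ProteinRecord("far", "F1", "s1", "WWWWYYYY"),
                ProteinRecord("twin1", "F2", "s1", "MKLVAEDE"),
                ProteinRecord("twin2", "F3", "s1", "MKLVAEDE")]
        t = build_guide_tree(recs)
        nwk = newick_string(t)
        assert "(twin1:0,twin2:0)" in nwk or "(twin2:0,twin1:0)" in nwk

    def test_duplicate_ids_rejected(self):
        recs = [ProteinRecord("a", "F1", "s1", "MKL"),
                ProteinRecord("a", "F2", "s2", "MKV")]
        with pytest.raises(ValidationError):
            build_guide_tree(recs)

    def test_recovers_ultrametric_topology(self):
        import numpy as np

        # ((a,b),(c,d)) with heights 1 and 3
        labels = ["a", "b", "c", "d"]
        d = np.array([[0, 2, 6, 6],
                      [2, 0, 6, 6],
                      [6, 6, 0, 2],
                      [6, 6, 2, 0]], dtype=float)
        recs = [ProteinRecord(l, f"F{l}", "s", "MKL") for l in labels]
        t = build_guide_tree(recs, distances=d)
        expect = tree_from_newick("((a:1,b:1):2,(c:1,d:1):2);")
        assert robinson_foulds(t, expect) == 0


class TestProgressiveAlign:
    def test_identical_sequences_align_gap_free(self):
        recs = [ProteinRecord(f"s{i}", f"F{i}", "sp", "MKLVAE") for i in range(3)]
        aln = progressive_align(recs)
        assert aln.seqs == ["MKLVAE"] * 3

    def test_indel_placed_at_missing_residue(self):
        recs = [ProteinRecord("a", "F1", "s", "ACDEF"),
                ProteinRecord("b", "F2", "s", "ACEF")]
        aln = progressive_align(recs)
        assert aln.seqs == ["ACDEF", "AC-EF"]

    def test_substitution_only_inputs_align_gap_free(self):
        rng = random.Random(7)
        base = "".join(rng.choices(AA, k=60))
        recs = []
        for i in range(5):
            seq = list(base)
            for _ in range(3):  # a few substitutions per sequence
                pos = rng.randrange(len(seq))
                seq[pos] = rng.choice(AA.replace(seq[pos], ""))
            recs.append(ProteinRecord(f"s{i}", f"F{i}", "sp", "".join(seq)))
        aln = progressive_align(recs)
        assert aln.width == 60
        assert all("-" not in s for s in aln.seqs)

    def test_low_divergence_orthologues_align_gap_free(self, small_dataset):
        _, records, _, _ = small_dataset
        fam = [r for r in records if r.family == "CHD5"]
        aln = progressive_align(fam)
        assert aln.width == len(fam[0].sequence)
        assert all("-" not in s for s in aln.seqs)

    def test_every_row_ungaps_to_its_input(self):
        recs = [ProteinRecord("a", "F1", "s", "MKWVLDEAA"),
                ProteinRecord("b", "F2", "s", "MKVLEAA"),
                ProteinRecord("c", "F3", "s", "MKWVLEA")]
        aln = progressive_align(recs)
        for r in recs:
            assert aln.ungapped(r.id) == r.sequence

    def test_deterministic_given_same_inputs(self):
        rng = random.Random(5)
        recs = [ProteinRecord(f"s{i}", f"F{i}", "sp",
                              "".join(rng.choices(AA, k=30)))
                for i in range(4)]
        assert progressive_align(recs).seqs == progressive_align(recs).seqs

    def test_progressive_never_beats_exhaustive_sum_of_pairs(self):
        # tiny instances where the exhaustive multiple-alignment optimum
        # is computable by enumerating all 3-way column compositions
        rng = random.Random(21)
        for _ in range(3):
            seqs = ["".join(rng.choices(AA, k=3)) for _ in range(3)]
            recs = [ProteinRecord(f"s{i}", f"F{i}", "sp", s)
                    for i, s in enumerate(seqs)]
            aln = progressive_align(recs)
            got = sum_of_pairs_score(aln.seqs, matrix_score,
                                     SCHEME.gap_open, SCHEME.gap_extend)
            best = _exhaustive_msa_optimum(seqs)
            assert got <= best + 1e-9


def _exhaustive_msa_optimum(seqs: list[str]) -> float:
    """Max sum-of-pairs score over all 3-sequence alignments (tiny inputs)."""
    n1, n2, n3 = (len(s) for s in seqs)
    best = float("-inf")
    stack = [((0, 0, 0), ["", "", ""])]
    while stack:
        (i, j, k), rows = stack.pop()
        if (i, j, k) == (n1, n2, n3):
            best = max(best, sum_of_pairs_score(
                rows, matrix_score, SCHEME.gap_open, SCHEME.gap_extend))
            continue
        for di in (0, 1):
            for dj in (0, 1):
                for dk in (0, 1):
                    if (di, dj, dk) == (0, 0, 0):
                        continue
                    if i + di > n1 or j + dj > n2 or k + dk > n3:
                        continue
                    cells = [
                        rows[0] + (seqs[0][i] if di else "-"),
                        rows[1] + (seqs[1][j] if dj else "-"),
                        rows[2] + (seqs[2][k] if dk else "-"),
                    ]
                    stack.append(((i + di, j + dj, k + dk), cells))
    return best


class TestPairwisePDistance:
    def test_identical_is_zero(self):
        assert pairwise_p_distance("MKLV", "MKLV") == 0.0

    def test_x_counts_as_difference(self):
        assert pairwise_p_distance("MXLV", "MXLV") == 0.25
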
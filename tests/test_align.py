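"""Aligner correctness against exact DP oracles and closed-form statistics."""

import numpy as np
import pytest
from Bio import Align
from hypothesis import given, settings
from hypothesis import strategies as st

from sympan.align import (AlignmentParams, LocalHit, SubstitutionMatrix,
                          coverage_fraction, evalue, global_percent_identity,
                          local_align, local_best_score)
from sympan.records import ProteinRecord
from sympan.simulate import AA20

REC = lambda locus, seq: ProteinRecord("s", locus, seq)


def oracle_aligner(matrix: SubstitutionMatrix, params: AlignmentParams,
                   mode: str) -> Align.PairwiseAligner:
    """Biopython's exact DP aligner with identical scoring (independent of
    the package's own kernels)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    sub = Align.substitution_matrices.Array(
        alphabet=matrix.alphabet, dims=2, data=matrix.scores.astype(float))
    aligner.substitution_matrix = sub
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def random_protein(rng, length):
    return "".join(rng.choice(list(AA20), size=length))


class TestLocalAlign:
    def test_self_alignment_full_span(self, blosum62, permissive_params):
        rec = REC("q", "MKTAYIAKQR")
        (hit,) = local_align(rec, rec, blosum62, permissive_params)[:1]
        assert hit.query_span == (0, 10)
        assert hit.subject_span == (0, 10)
        assert hit.identity_fraction == 1.0
        assert hit.similarity_fraction == 1.0

    def test_textbook_pair_matches_dp_oracle(self, blosum62, permissive_params):
        a, b = REC("a", "HEAGAWGHEE"), REC("b", "PAWHEAE")
        hits = local_align(a, b, blosum62, permissive_params)
        oracle = oracle_aligner(blosum62, permissive_params, "local")
        assert hits[0].score == oracle.score(a.seq, b.seq) == 17

    def test_scores_match_oracle_on_seeded_pairs(self, blosum62, permissive_params):
        oracle = oracle_aligner(blosum62, permissive_params, "local")
        rng = np.random.default_rng(42)
        for _ in range(60):
            a = random_protein(rng, rng.integers(8, 31))
            b = random_protein(rng, rng.integers(8, 31))
            assert local_best_score(a, b, blosum62, permissive_params) == \
                int(oracle.score(a, b))

    def test_top_score_symmetric(self, blosum62, permissive_params):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = random_protein(rng, 25)
            b = random_protein(rng, 40)
            assert local_best_score(a, b, blosum62, permissive_params) == \
                local_best_score(b, a, blosum62, permissive_params)

    def test_random_pairs_rarely_pass_evalue_threshold(self, blosum62, params):
        rng = np.random.default_rng(3)
        n_hits = sum(
            bool(local_align(REC("a", random_protein(rng, 50)),
                             REC("b", random_protein(rng, 50)),
                             blosum62, params))
            for _ in range(100))
        assert n_hits <= 5

    def test_identity_never_exceeds_similarity(self, blosum62, permissive_params):
        rng = np.random.default_rng(11)
        for _ in range(25):
            a = REC("a", random_protein(rng, 60))
            b = REC("b", random_protein(rng, 60))
            for hit in local_align(a, b, blosum62, permissive_params):
                assert 0 <= hit.identity_fraction <= hit.similarity_fraction <= 1

    def test_bad_residue_names_locus_and_position(self, blosum62, params):
        with pytest.raises(ValueError, match=r"position 2 of badlocus"):
            local_align(REC("badlocus", "MK1T"), REC("b", "MKT"),
                        blosum62, params)

    def test_empty_sequence_rejected(self, blosum62, params):
        with pytest.raises(ValueError):
            local_align(REC("a", ""), REC("b", "MKT"), blosum62, params)


class TestEvalue:
    def test_score_zero_gives_kmn(self, params):
        assert evalue(0, 100, 200, params) == pytest.approx(
            params.karlin_K * 100 * 200)

    def test_monotone_decreasing_in_score(self, params):
        assert evalue(50, 100, 100, params) < evalue(40, 100, 100, params)

    def test_closed_form(self, params):
        expect = 0.041 * 100 * 100 * np.exp(-0.267 * 40)
        assert evalue(40, 100, 100, params) == pytest.approx(expect, rel=1e-12)

    def test_nonpositive_length_rejected(self, params):
        with pytest.raises(ValueError):
            evalue(10, 0, 100, params)


def make_hit(qspan, sspan, sim=1.0, ident=1.0):
    return LocalHit("q", "s", 100, 1e-10, qspan, sspan, ident, sim,
                    n_columns=qspan[1] - qspan[0])


class TestCoverage:
    def test_single_interval(self):
        assert coverage_fraction([make_hit((0, 80), (0, 80))], 100) == \
            pytest.approx(0.80)

    def test_overlapping_intervals_counted_once(self):
        hits = [make_hit((0, 50), (0, 50)), make_hit((40, 90), (40, 90))]
        assert coverage_fraction(hits, 100) == pytest.approx(0.90)

    def test_empty_hits(self):
        assert coverage_fraction([], 100) == 0.0

    def test_out_of_bounds_span(self):
        with pytest.raises(ValueError):
            coverage_fraction([make_hit((0, 120), (0, 120))], 100)

    @given(st.lists(st.tuples(st.integers(0, 99), st.integers(1, 40)),
                    min_size=1, max_size=6))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_matches_position_set_oracle(self, raw):
        spans = [(lo, min(100, lo + w)) for lo, w in raw if lo + w <= 100]
        if not spans:
            return
        hits = [make_hit(s, s) for s in spans]
        oracle = len({p for lo, hi in spans for p in range(lo, hi)}) / 100
        assert coverage_fraction(hits, 100) == pytest.approx(oracle)


class TestGlobalIdentity:
    def test_identical(self, blosum62, params):
        assert global_percent_identity("ACDE", "ACDE", blosum62, params) == 100.00

    def test_single_mismatch(self, blosum62, params):
        assert global_percent_identity("ACDE", "ACDF", blosum62, params) == 75.00

    def test_no_identity(self, blosum62, params):
        assert global_percent_identity("AAAA", "WWWW", blosum62, params) == 0.00

    def test_empty_rejected(self, blosum62, params):
        with pytest.raises(ValueError):
            global_percent_identity("", "ACDE", blosum62, params)

    def test_score_matches_global_oracle(self, blosum62, params):
        from sympan.align import global_align

        oracle = oracle_aligner(blosum62, params, "global")
        rng = np.random.default_rng(13)
        for _ in range(40):
            a = random_protein(rng, rng.integers(5, 30))
            b = random_protein(rng, rng.integers(5, 30))
            assert global_align(a, b, blosum62, params).score == \
                int(oracle.score(a, b))


class TestSubstitutionMatrix:
    def test_blosum62_diagonal_positive_and_symmetric(self, blosum62):
        for aa in AA20:
            assert blosum62.score(aa, aa) > 0
        assert blosum62.score("K", "R") == blosum62.score("R", "K") == 2

    def test_x_scores_zero_policy(self, blosum62):
        assert all(blosum62.score("X", aa) == 0 for aa in AA20)

    def test_ncbi_text_round_trip(self, tmp_path, blosum62):
        from Bio.Align import substitution_matrices

        path = tmp_path / "BLOSUM62.txt"
        path.write_text(str(substitution_matrices.load("BLOSUM62")))
        m = SubstitutionMatrix.from_ncbi_text(path)
        assert m.score("W", "W") == 11
        assert m.alphabet == blosum62.alphabet
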
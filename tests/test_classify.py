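import random
from fractions import Fraction

import pytest

from conftest import make_column_alignment, oracle_classify, random_column
from sigchar.classify import (
    CharClass,
    compute_position_metrics,
    classify,
    is_candidate,
    is_signature,
    rank_alignment,
    rank_positions,
)
from sigchar.errors import SigcharError
from sigchar.vectors import CharacterStateVector, build_state_vector


def vec(*counts):
    return CharacterStateVector(tuple(counts))


class TestIsCandidate:
    def test_uniform_query(self):
        assert is_candidate(vec(0, 0, 3, 0, 0, 0))

    def test_multi_state_query(self):
        assert not is_candidate(vec(2, 1, 0, 0, 0, 0))

    def test_all_n_query(self):
        assert not is_candidate(vec(0, 0, 0, 0, 0, 3))

    def test_single_n_breaks_candidacy(self):
        assert not is_candidate(vec(0, 0, 2, 0, 0, 1))

    def test_uniform_gap_is_candidate(self):
        assert is_candidate(vec(0, 0, 0, 0, 3, 0))


class TestClassify:
    def test_worked_example_p1_binary(self, worked_aln, worked_part):
        q = build_state_vector(worked_aln, worked_part.query_ids, 1)
        r = build_state_vector(worked_aln, worked_part.reference_ids, 1)
        assert classify(q, r) is CharClass.BINARY

    def test_asymmetric(self):
        assert classify(vec(0, 0, 3, 0, 0, 0),
                        vec(2, 0, 0, 2, 0, 0)) is CharClass.ASYMMETRIC

    def test_noisy(self):
        # shared T => d < 1; r-rank 3 => noisy
        assert classify(vec(0, 0, 0, 3, 0, 0),
                        vec(1, 0, 0, 2, 1, 0)) is CharClass.NOISY

    def test_conserved(self):
        assert classify(vec(3, 0, 0, 0, 0, 0),
                        vec(4, 0, 0, 0, 0, 0)) is CharClass.CONSERVED

    def test_non_candidate(self):
        assert classify(vec(2, 1, 0, 0, 0, 0),
                        vec(4, 0, 0, 0, 0, 0)) is CharClass.NON_CANDIDATE

    def test_reference_n_cannot_match_candidate(self):
        # candidate query G vs reference {G, N}: shared G => noisy
        assert classify(vec(0, 0, 3, 0, 0, 0),
                        vec(0, 0, 2, 0, 0, 2)) is CharClass.NOISY
        # reference all N is disjoint from any candidate query state
        assert classify(vec(0, 0, 3, 0, 0, 0),
                        vec(0, 0, 0, 0, 0, 4)) is CharClass.BINARY


class TestPositionMetrics:
    def test_p5(self, worked_aln, worked_part):
        m = compute_position_metrics(worked_aln, worked_part, 5)
        assert m.d_power == 1
        assert m.q_rank == 1
        assert m.r_rank == 2
        assert m.char_class is CharClass.ASYMMETRIC
        assert m.is_signature
        assert not m.ref_has_missing

    def test_p16_conserved(self, worked_aln, worked_part):
        m = compute_position_metrics(worked_aln, worked_part, 16)
        assert m.char_class is CharClass.CONSERVED
        assert m.d_power == Fraction(1, 7)
        assert not is_signature(m)

    def test_p20_noisy(self, worked_aln, worked_part):
        m = compute_position_metrics(worked_aln, worked_part, 20)
        assert m.char_class is CharClass.NOISY
        assert not is_signature(m)

    def test_p8_not_signature(self, worked_aln, worked_part):
        assert not is_signature(
            compute_position_metrics(worked_aln, worked_part, 8))

    def test_ref_has_missing_flag(self):
        aln, part = make_column_alignment("GGG", "GN")
        m = compute_position_metrics(aln, part, 1)
        assert m.ref_has_missing
        assert m.char_class is CharClass.NOISY


class TestRanking:
    def test_lexicographic_order(self, worked_aln, worked_part):
        rows = [compute_position_metrics(worked_aln, worked_part, p)
                for p in (5, 1, 8)]  # (1,1,2), (1,1,1), (<1,1,2)
        ranked = rank_positions(rows)
        assert [r.position for r in ranked.rows] == [1, 5, 8]

    def test_tie_break_by_position(self, worked_aln, worked_part):
        rows = [compute_position_metrics(worked_aln, worked_part, p)
                for p in (17, 15, 16)]  # identical metrics
        ranked = rank_positions(rows)
        assert [r.position for r in ranked.rows] == [15, 16, 17]

    def test_single_row(self, worked_aln, worked_part):
        row = compute_position_metrics(worked_aln, worked_part, 1)
        assert rank_positions([row]).rows == (row,)

    def test_duplicate_positions_rejected(self, worked_aln, worked_part):
        row = compute_position_metrics(worked_aln, worked_part, 1)
        with pytest.raises(SigcharError):
            rank_positions([row, row])

    def test_full_table_covers_every_position(self, worked_aln, worked_part):
        ranked = rank_alignment(worked_aln, worked_part)
        assert sorted(r.position for r in ranked.rows) == list(range(1, 25))

    def test_class_precedence(self, worked_aln, worked_part):
        ranked = rank_alignment(worked_aln, worked_part)
        order = {CharClass.BINARY: 0, CharClass.ASYMMETRIC: 1,
                 CharClass.NOISY: 2}
        seen = [order[r.char_class] for r in ranked.rows
                if r.char_class in order]
        assert seen == sorted(seen)

    def test_signature_rows_precede_low_d_rows(self, worked_aln, worked_part):
        ranked = rank_alignment(worked_aln, worked_part)
        last_sig = max(i for i, r in enumerate(ranked.rows) if r.is_signature)
        first_low = min(i for i, r in enumerate(ranked.rows)
                        if r.d_power < 1)
        assert last_sig < first_low

    def test_sorted_by_key(self, worked_aln, worked_part):
        ranked = rank_alignment(worked_aln, worked_part)
        keys = [(-r.d_power, r.q_rank, r.r_rank, r.position)
                for r in ranked.rows]
        assert keys == sorted(keys)


class TestOracleEquivalence:
    """Vector-metric classification vs set-based brute force on raw columns."""

    def test_randomized_columns(self):
        rng = random.Random(20260903)
        for _ in range(2000):
            nq = rng.randint(1, 6)
            nr = rng.randint(1, 6)
            qs = random_column(rng, nq)
            rs = random_column(rng, nr)
            aln, part = make_column_alignment(qs, rs)
            m = compute_position_metrics(aln, part, 1)
            assert m.char_class.value == oracle_classify(qs, rs), (qs, rs)

    def test_exhaustive_tiny_groups(self):
        from itertools import product
        states = "AGTN-"
        for qs in ("A", "AA", "AG", "AN"):
            for rs_tuple in product(states, repeat=2):
                rs = "".join(rs_tuple)
                aln, part = make_column_alignment(qs, rs)
                m = compute_position_metrics(aln, part, 1)
                assert m.char_class.value == oracle_classify(qs, rs)
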
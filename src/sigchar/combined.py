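"""Combined (two-position) characters within a k-window.

Noisy candidate positions, individually unable to separate the groups,
may pair into jointly diagnostic characters: the state vectors of an
ordered position pair live in 36 dimensions (all ordered symbol pairs)
and are ranked and classified with the same metrics as single positions.
Only pairs of noisy candidates (i, j) with |i - j| < k are examined.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from .alignment import ALPHABET, Alignment, GroupPartition
from .classify import CharClass, RankedTable, classify
from .errors import ParameterError, UndefinedInputError
from .vectors import (
    PAIR_ALPHABET,
    CharacterStateVector,
    ConsensusState,
    build_state_vector,
    consensus_state,
    discriminative_power,
    vector_rank,
)


@dataclass(frozen=True)
class CombinedCharacter:
    """A classified pair of noisy candidate positions (i < j)."""

    i: int
    j: int
    d_power: Fraction
    q_rank: int
    r_rank: int
    query_pair: ConsensusState
    reference_pair: ConsensusState
    char_class: CharClass

    @property
    def is_signature(self) -> bool:
        return self.char_class in (CharClass.BINARY, CharClass.ASYMMETRIC)


def enumerate_pairs(noisy_positions: Sequence[int],
                    k: int) -> list[tuple[int, int]]:
    """All pairs i < j from a sorted position list with j - i < k."""
    if k < 1:
        raise ParameterError(f"k-window must be >= 1, got {k}")
    positions = list(noisy_positions)
    if positions != sorted(set(positions)):
        raise ParameterError("noisy positions must be strictly increasing")
    return [(i, j)
            for a, i in enumerate(positions)
            for j in positions[a + 1:]
            if j - i < k]


def build_pair_vector(aln: Alignment, ids: Iterable[str], i: int,
                      j: int) -> CharacterStateVector:
    """36-dimensional count vector of ordered state pairs at (i, j).

    Written generically over a tuple of positions so that extension to
    longer combinations only needs a wider alphabet.
    """
    ids = tuple(ids)
    if not ids:
        raise UndefinedInputError("empty id set")
    # validates bounds for both positions
    for pos in (i, j):
        build_state_vector(aln, ids[:1], pos)
    index = {s: n for n, s in enumerate(PAIR_ALPHABET)}
    counts = [0] * len(PAIR_ALPHABET)
    for sid in ids:
        seq = aln.records[sid]
        counts[index[seq[i - 1] + seq[j - 1]]] += 1
    return CharacterStateVector(tuple(counts), state_list=PAIR_ALPHABET)


def classify_pair(q2: CharacterStateVector,
                  r2: CharacterStateVector) -> tuple[Fraction, int, int, CharClass]:
    """Metrics and class of a pair vector couple (same rules as singles)."""
    cls = classify(q2, r2)
    return (discriminative_power(q2, r2), vector_rank(q2),
            vector_rank(r2), cls)


def combine_positions(aln: Alignment, part: GroupPartition, i: int,
                      j: int) -> CombinedCharacter:
    """Build and classify one combined character."""
    q2 = build_pair_vector(aln, part.query_ids, i, j)
    r2 = build_pair_vector(aln, part.reference_ids, i, j)
    d, q_rank, r_rank, cls = classify_pair(q2, r2)
    return CombinedCharacter(
        i=i, j=j, d_power=d, q_rank=q_rank, r_rank=r_rank,
        query_pair=consensus_state(q2),
        reference_pair=consensus_state(r2),
        char_class=cls)


def find_combined_characters(aln: Alignment, part: GroupPartition,
                             ranked: RankedTable,
                             k: int) -> list[CombinedCharacter]:
    """Enumerate and classify all in-window pairs of noisy candidates.

    Results are sorted by (d-power descending, q-rank ascending, r-rank
    ascending), then (i, j) ascending. Asymmetric pairs are the
    diagnostic combinations; other classes are retained for audit.
    """
    noisy = sorted(r.position for r in ranked.rows
                   if r.char_class is CharClass.NOISY)
    out = [combine_positions(aln, part, i, j)
           for i, j in enumerate_pairs(noisy, k)]
    out.sort(key=lambda c: (-c.d_power, c.q_rank, c.r_rank, c.i, c.j))
    return out
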
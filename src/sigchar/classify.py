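"""Candidacy, classification, and the diagnostic relevance ranking.

A position is a candidate character iff its query group is uniform in a
single state that is not N (missing information). Candidates fall into
four classes by exact thresholds on (d-power, q-rank, r-rank):

========== ======= ====== ======
class      d-power q-rank r-rank
========== ======= ====== ======
binary     1       1      1
asymmetric 1       1      >1
noisy      <1      1      >1
conserved  <1      1      1
========== ======= ====== ======

Binary and asymmetric candidates (d-power exactly 1) are signature
characters: they separate every query member from every reference
member. Non-candidate positions are retained in the ranking but carry
the class label ``non_candidate``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from .alignment import Alignment, GroupPartition
from .errors import DimensionError, SigcharError
from .vectors import (
    CharacterStateVector,
    ConsensusState,
    build_state_vector,
    consensus_state,
    discriminative_power,
    vector_rank,
)


class CharClass(enum.Enum):
    BINARY = "binary"
    ASYMMETRIC = "asymmetric"
    NOISY = "noisy"
    CONSERVED = "conserved"
    NON_CANDIDATE = "non_candidate"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Classes whose members are signature characters (d-power exactly 1).
SIGNATURE_CLASSES = frozenset({CharClass.BINARY, CharClass.ASYMMETRIC})


@dataclass(frozen=True)
class PositionMetrics:
    """All per-position quantities entering the ranked table."""

    position: int
    d_power: Fraction
    q_rank: int
    r_rank: int
    query_state: ConsensusState
    reference_state: ConsensusState
    char_class: CharClass
    is_signature: bool
    ref_has_missing: bool


@dataclass(frozen=True)
class RankedTable:
    """Rows in diagnostic relevance order, one per alignment position."""

    rows: tuple[PositionMetrics, ...]

    def signature_rows(self) -> tuple[PositionMetrics, ...]:
        return tuple(r for r in self.rows if r.is_signature)

    def rows_of_class(self, cls: CharClass) -> tuple[PositionMetrics, ...]:
        return tuple(r for r in self.rows if r.char_class is cls)

    def by_position(self, position: int) -> PositionMetrics:
        for row in self.rows:
            if row.position == position:
                return row
        raise KeyError(position)


def is_candidate(q: CharacterStateVector) -> bool:
    """Uniform query state that is not missing information."""
    n_index = q.state_list.index("N") if "N" in q.state_list else None
    if n_index is not None and q.counts[n_index] > 0:
        return False
    return vector_rank(q) == 1


def classify(q: CharacterStateVector,
             r: CharacterStateVector) -> CharClass:
    """Classify one (query, reference) vector pair.

    The d = 1 threshold is evaluated as the exact integer identity
    "disjoint non-zero support", equivalent to the normalized L1
    distance reaching 1.
    """
    if q.state_list != r.state_list:
        raise DimensionError("vectors over different state lists")
    if not is_candidate(q):
        return CharClass.NON_CANDIDATE
    disjoint = all(
        qc == 0 or rc == 0 for qc, rc in zip(q.counts, r.counts))
    r_rank = vector_rank(r)
    if disjoint:
        return CharClass.BINARY if r_rank == 1 else CharClass.ASYMMETRIC
    return CharClass.CONSERVED if r_rank == 1 else CharClass.NOISY


def is_signature(m: PositionMetrics) -> bool:
    """Signature characters are exactly the binary and asymmetric rows."""
    return m.char_class in SIGNATURE_CLASSES


def compute_position_metrics(aln: Alignment, part: GroupPartition,
                             position: int) -> PositionMetrics:
    """Build both group vectors at ``position`` and derive all metrics."""
    q = build_state_vector(aln, part.query_ids, position)
    r = build_state_vector(aln, part.reference_ids, position)
    char_class = classify(q, r)
    n_index = r.state_list.index("N")
    return PositionMetrics(
        position=position,
        d_power=discriminative_power(q, r),
        q_rank=vector_rank(q),
        r_rank=vector_rank(r),
        query_state=consensus_state(q),
        reference_state=consensus_state(r),
        char_class=char_class,
        is_signature=char_class in SIGNATURE_CLASSES,
        ref_has_missing=r.counts[n_index] > 0,
    )


def ranking_key(m: PositionMetrics) -> tuple:
    """Lexicographic sort key: d-power descending, q-rank ascending,
    r-rank ascending, then position ascending for determinism."""
    return (-m.d_power, m.q_rank, m.r_rank, m.position)


def rank_positions(rows: Iterable[PositionMetrics]) -> RankedTable:
    """Order metric rows into the diagnostic relevance ranking."""
    rows = tuple(rows)
    positions = [r.position for r in rows]
    if len(set(positions)) != len(positions):
        dupes = sorted({p for p in positions if positions.count(p) > 1})
        raise SigcharError(f"duplicate positions in ranking input: {dupes}")
    return RankedTable(rows=tuple(sorted(rows, key=ranking_key)))


def rank_alignment(aln: Alignment, part: GroupPartition) -> RankedTable:
    """Metrics for every alignment position, in relevance order."""
    return rank_positions(
        compute_position_metrics(aln, part, p)
        for p in range(1, aln.length + 1))
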
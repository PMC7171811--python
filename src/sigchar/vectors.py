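"""Character state vectors and their ranking metrics.

Every alignment column is summarized, per group, as a count vector over
the ordered state list (6 symbols for single positions, 36 ordered
symbol pairs for combined positions). Three metrics drive ranking and
classification: discriminative power (normalized L1 distance between the
query and reference vectors), query rank and reference rank (number of
non-zero dimensions of the respective vector).

Discriminative power is computed as an exact rational from the integer
counts, so the d = 1 / d < 1 distinction used in classification is an
exact integer test, never a float comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable

from .alignment import ALPHABET, Alignment
from .errors import BoundsError, DimensionError, UndefinedInputError

#: Ordered state pairs for combined (two-position) characters, row-major
#: over the single-position alphabet: AA, AC, ..., NN.
PAIR_ALPHABET: tuple[str, ...] = tuple(
    a + b for a in ALPHABET for b in ALPHABET)


@dataclass(frozen=True)
class CharacterStateVector:
    """Counts per symbol of an ordered state list."""

    counts: tuple[int, ...]
    state_list: tuple[str, ...] = ALPHABET

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.state_list):
            raise DimensionError(
                f"{len(self.counts)} counts for "
                f"{len(self.state_list)} states")
        if any(c < 0 for c in self.counts):
            raise ValueError("negative count")

    @property
    def l1_norm(self) -> int:
        return sum(self.counts)

    def count_of(self, state: str) -> int:
        return self.counts[self.state_list.index(state)]


@dataclass(frozen=True)
class ConsensusState:
    """Uniform or prevalent state of a vector, for display."""

    state: str
    is_uniform: bool


def build_state_vector(aln: Alignment, ids: Iterable[str],
                       position: int) -> CharacterStateVector:
    """Count states at a 1-based ``position`` over the sequences ``ids``."""
    ids = tuple(ids)
    if not ids:
        raise UndefinedInputError("empty id set")
    if not 1 <= position <= aln.length:
        raise BoundsError(f"position {position} outside [1, {aln.length}]")
    counts = [0] * len(ALPHABET)
    index = {s: i for i, s in enumerate(ALPHABET)}
    for sid in ids:
        counts[index[aln.records[sid][position - 1]]] += 1
    return CharacterStateVector(tuple(counts))


def discriminative_power(q: CharacterStateVector,
                         r: CharacterStateVector) -> Fraction:
    """Normalized L1 distance between two count vectors, in [0, 1].

    Equals 1 exactly when the vectors have disjoint non-zero support and
    0 exactly when they are identical.
    """
    if len(q.counts) != len(r.counts) or q.state_list != r.state_list:
        raise DimensionError("vectors over different state lists")
    denom = q.l1_norm + r.l1_norm
    if q.l1_norm == 0 or r.l1_norm == 0:
        raise UndefinedInputError(
            "discriminative power undefined for a zero vector")
    num = sum(abs(a - b) for a, b in zip(q.counts, r.counts))
    return Fraction(num, denom)


def vector_rank(v: CharacterStateVector) -> int:
    """Number of strictly positive dimensions."""
    return sum(1 for c in v.counts if c > 0)


def consensus_state(v: CharacterStateVector) -> ConsensusState:
    """Most frequent state; ties broken by state-list order (earliest wins)."""
    if v.l1_norm == 0:
        raise UndefinedInputError("consensus undefined for a zero vector")
    best = max(range(len(v.counts)), key=lambda i: (v.counts[i], -i))
    return ConsensusState(state=v.state_list[best],
                          is_uniform=vector_rank(v) == 1)
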
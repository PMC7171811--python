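"""Per-column entropy profile of the full alignment.

Shannon entropy in bits over the informative states A, C, G, T and gap.
N (missing information) is excluded by default and the remaining
frequencies renormalized; an all-N column has entropy 0. Setting
``include_missing=True`` counts N as a sixth informative state instead.

The profile always covers every alignment sequence, including ones that
belong to neither analysis group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .alignment import ALPHABET, Alignment
from .errors import BoundsError

#: States that carry information for the entropy profile (N excluded).
INFORMATIVE_STATES: tuple[str, ...] = ("A", "C", "G", "T", "-")


@dataclass(frozen=True)
class EntropyProfile:
    values: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.values)

    @property
    def max_value(self) -> float:
        return max(self.values) if self.values else 0.0


def column_entropy(aln: Alignment, position: int, *,
                   include_missing: bool = False) -> float:
    """Shannon entropy (bits) of one column across all sequences."""
    if not 1 <= position <= aln.length:
        raise BoundsError(f"position {position} outside [1, {aln.length}]")
    states = ALPHABET if include_missing else INFORMATIVE_STATES
    column = aln.column(position)
    counts = [sum(1 for c in column if c == s) for s in states]
    total = sum(counts)
    if total == 0:
        return 0.0
    h = -sum((c / total) * math.log2(c / total) for c in counts if c > 0)
    return h


def entropy_profile(aln: Alignment, *,
                    include_missing: bool = False) -> EntropyProfile:
    """Column entropy at every position, in order."""
    return EntropyProfile(values=tuple(
        column_entropy(aln, p, include_missing=include_missing)
        for p in range(1, aln.length + 1)))
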
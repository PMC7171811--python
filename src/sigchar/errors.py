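"""Exception hierarchy for sigchar.

All library errors derive from :class:`SigcharError` so callers (and the
CLI) can catch a single base class.
"""


class SigcharError(Exception):
    """Base class for all sigchar errors."""


class AlignmentError(SigcharError):
    """Invalid alignment input (shape, ids, characters)."""


class AlignmentShapeError(AlignmentError):
    """Sequences of unequal length."""


class DuplicateIdError(AlignmentError):
    """Duplicate sequence id or leaf label."""


class InvalidCharacterError(AlignmentError):
    """Character outside the recognized state set."""


class TreeFormatError(SigcharError):
    """Unparseable Newick input."""


class UnknownIdError(SigcharError):
    """Group specification names an id absent from the alignment."""


class PartitionError(SigcharError):
    """Query/reference groups overlap or are empty."""


class BoundsError(SigcharError):
    """Position index outside the alignment."""


class DimensionError(SigcharError):
    """Character state vectors over mismatched state lists."""


class UndefinedInputError(SigcharError):
    """Operation undefined for the given input (e.g. zero vector)."""


class ParameterError(SigcharError):
    """Invalid analysis parameter (e.g. k < 1)."""


class PlanError(SigcharError):
    """Infeasible planted-class plan for a random fixture."""
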
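"""Alignment and tree input, state normalization, and group resolution.

The state alphabet is fixed to the ordered list ``('A', 'C', 'G', 'T',
'-', 'N')``: the four nucleotides, the gap (deletion) state, and N for
missing information. Lowercase letters, ``U`` (RNA) and ``.`` (alternate
gap) are normalized on input; IUPAC degeneracy codes are either masked to
N (default) or rejected, depending on the ambiguity policy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
from Bio import SeqIO

from .errors import (
    AlignmentError,
    AlignmentShapeError,
    BoundsError,
    DuplicateIdError,
    InvalidCharacterError,
    PartitionError,
    TreeFormatError,
    UnknownIdError,
)

logger = logging.getLogger("sigchar")

#: Fixed ordered state list; vector dimensions follow this order.
ALPHABET: tuple[str, ...] = ("A", "C", "G", "T", "-", "N")

#: IUPAC nucleotide degeneracy codes (not part of the state alphabet).
IUPAC_AMBIGUITY: frozenset[str] = frozenset("RYSWKMBDHV")

_DIRECT = {"U": "T", ".": "-"}


def normalize_state(char: str, *, on_ambiguity: str = "mask",
                    context: str = "") -> str:
    """Map one raw character onto the 6-state alphabet.

    ``on_ambiguity`` is ``"mask"`` (IUPAC degeneracy codes become N, with
    a warning) or ``"strict"`` (they raise
    :class:`~sigchar.errors.InvalidCharacterError`).
    """
    c = char.upper()
    c = _DIRECT.get(c, c)
    if c in ALPHABET:
        return c
    if c in IUPAC_AMBIGUITY:
        if on_ambiguity == "strict":
            raise InvalidCharacterError(
                f"ambiguity code {char!r} not allowed under strict policy"
                + (f" ({context})" if context else ""))
        logger.warning("masking ambiguity code %r to N%s", char,
                       f" ({context})" if context else "")
        return "N"
    raise InvalidCharacterError(
        f"unrecognized character {char!r}"
        + (f" ({context})" if context else ""))


def normalize_sequence(seq: str, *, on_ambiguity: str = "mask",
                       seq_id: str = "") -> str:
    """Normalize a whole state string (see :func:`normalize_state`)."""
    out = []
    for pos, char in enumerate(seq, start=1):
        out.append(normalize_state(
            char, on_ambiguity=on_ambiguity,
            context=f"id={seq_id!r}, position={pos}"))
    return "".join(out)


@dataclass(frozen=True)
class Alignment:
    """An aligned set of equal-length nucleotide state strings.

    ``records`` preserves input order and maps unique sequence ids to
    normalized state strings over :data:`ALPHABET`.
    """

    records: Mapping[str, str]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment must contain at least one record")
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) != 1:
            offenders = sorted(
                {i for i, s in self.records.items()
                 if len(s) != len(next(iter(self.records.values())))})
            raise AlignmentShapeError(
                f"unequal sequence lengths {sorted(lengths)}; "
                f"offending ids include: {', '.join(offenders)}")
        length = lengths.pop()
        if length < 1:
            raise AlignmentShapeError("alignment length must be >= 1")
        for sid, seq in self.records.items():
            if not sid:
                raise AlignmentError("empty sequence id")
            bad = [c for c in seq if c not in ALPHABET]
            if bad:
                raise InvalidCharacterError(
                    f"non-normalized character {bad[0]!r} in record {sid!r}")
        object.__setattr__(self, "length", length)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.records)

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    def column(self, position: int, ids: Optional[Iterable[str]] = None) -> str:
        """States at a 1-based ``position``, for ``ids`` (default: all)."""
        if not 1 <= position <= self.length:
            raise BoundsError(
                f"position {position} outside [1, {self.length}]")
        sel = self.ids if ids is None else tuple(ids)
        return "".join(self.records[i][position - 1] for i in sel)


@dataclass(frozen=True)
class GroupPartition:
    """Disjoint, non-empty query and reference id sets of one alignment."""

    query_ids: frozenset[str]
    reference_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.query_ids:
            raise PartitionError("query group is empty")
        if not self.reference_ids:
            raise PartitionError("reference group is empty")
        overlap = self.query_ids & self.reference_ids
        if overlap:
            raise PartitionError(
                "query and reference groups overlap: "
                + ", ".join(sorted(overlap)))


class PhyloTree:
    """Thin wrapper around a rooted dendropy tree used for group selection.

    Only the topology and labels are interpreted; branch lengths and
    support values are ignored.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()
                  if leaf.taxon is not None]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise DuplicateIdError(
                "duplicate leaf labels: " + ", ".join(sorted(dupes)))
        self._leaf_labels = tuple(labels)

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return self._leaf_labels

    def _preorder_nodes(self) -> list:
        return list(self._tree.preorder_node_iter())

    def leaves_under(self, selector: str) -> frozenset[str]:
        """Leaf labels under the node named ``selector``.

        ``selector`` is matched against leaf taxon labels and internal
        node labels; if no label matches and the selector is an integer,
        it is taken as a stable preorder node index (0 = root).
        """
        selector = selector.strip()
        for node in self._tree.preorder_node_iter():
            label = node.taxon.label if node.taxon else node.label
            if label is not None and label.strip() == selector:
                return frozenset(
                    leaf.taxon.label for leaf in node.leaf_iter())
        if selector.lstrip("-").isdigit():
            nodes = self._preorder_nodes()
            idx = int(selector)
            if 0 <= idx < len(nodes):
                return frozenset(
                    leaf.taxon.label for leaf in nodes[idx].leaf_iter())
        raise UnknownIdError(f"no tree node matches selector {selector!r}")


def read_alignment(path, on_ambiguity: str = "mask") -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    States are normalized (lowercase to uppercase, U to T, ``.`` to gap);
    IUPAC degeneracy codes are handled per ``on_ambiguity``. Raises on
    unequal lengths, duplicate ids, or unrecognized characters.
    """
    if on_ambiguity not in ("mask", "strict"):
        raise ValueError(f"unknown ambiguity policy {on_ambiguity!r}")
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = rec.id.strip()
        if sid in records:
            raise DuplicateIdError(f"duplicate sequence id {sid!r}")
        records[sid] = normalize_sequence(
            str(rec.seq), on_ambiguity=on_ambiguity, seq_id=sid)
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    return Alignment(records)


def write_alignment(aln: Alignment, path) -> None:
    """Write an alignment back to FASTA (round-trips with read)."""
    with open(path, "w") as fh:
        for sid, seq in aln.records.items():
            fh.write(f">{sid}\n{seq}\n")


def _parse_newick(source_kwargs: dict, what: str) -> PhyloTree:
    try:
        tree = dendropy.Tree.get(
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            **source_kwargs)
    except Exception as exc:  # dendropy raises several parse error types
        if "Duplicate taxon labels" in str(exc):
            raise DuplicateIdError(
                f"duplicate leaf labels in {what}: {exc}") from exc
        raise TreeFormatError(f"cannot parse Newick {what}: {exc}") from exc
    return PhyloTree(tree)


def read_tree(path) -> PhyloTree:
    """Read a Newick tree, preserving leaf labels verbatim."""
    return _parse_newick({"path": str(path)}, f"file {path}")


def tree_from_string(newick: str) -> PhyloTree:
    """Parse a Newick string (convenience for tests and fixtures)."""
    return _parse_newick({"data": newick}, "string")


def _parse_id_list(spec: str) -> frozenset[str]:
    ids = frozenset(t.strip() for t in spec.split(",") if t.strip())
    if not ids:
        raise PartitionError(f"group specification {spec!r} resolves to no ids")
    return ids


def resolve_groups(
    aln: Alignment,
    query_spec: str,
    reference_spec: Optional[str] = None,
    tree: Optional[PhyloTree] = None,
    *,
    query_is_node: bool = False,
    reference_is_node: bool = False,
) -> GroupPartition:
    """Resolve group specifications into a validated partition.

    A spec is either a comma-separated id list or, with
    ``*_is_node=True`` and a tree supplied, a tree-node selector whose
    subtree leaves form the group. An absent reference spec defaults to
    the complement of the query set within the alignment ids.
    """
    known = set(aln.ids)

    def resolve(spec: str, is_node: bool) -> frozenset[str]:
        if is_node:
            if tree is None:
                raise UnknownIdError(
                    "tree-node selector given but no tree supplied")
            return tree.leaves_under(spec)
        return _parse_id_list(spec)

    query_ids = resolve(query_spec, query_is_node)
    if reference_spec is None:
        reference_ids = frozenset(known - query_ids)
    else:
        reference_ids = resolve(reference_spec, reference_is_node)

    unknown = sorted((query_ids | reference_ids) - known)
    if unknown:
        raise UnknownIdError(
            "ids not present in alignment: " + ", ".join(unknown))
    return GroupPartition(query_ids=query_ids, reference_ids=reference_ids)
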
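"""Deterministic test fixtures: the worked example and planted-class
random alignments.

``generate_worked_example`` reconstructs a 7-sequence, 24-column
alignment in which ten columns realize a prescribed class layout (one
binary, two asymmetric, four noisy, three conserved) and columns 19/20
pair into one jointly diagnostic combined character while 19/23 and
20/23 do not. The constrained columns are fixed by those requirements;
filler columns are deterministic non-candidates (non-uniform query).

``generate_random_fixture`` builds seeded alignments in which each
planned column provably realizes a requested class, constructed directly
from the set-based class definitions, for planted-recovery testing.
"""

from __future__ import annotations

import random
from typing import Mapping, Optional

from .alignment import Alignment, GroupPartition, PhyloTree, tree_from_string
from .classify import CharClass
from .errors import PlanError

QUERY_IDS = ("q1", "q2", "q3")
REFERENCE_IDS = ("r1", "r2", "r3", "r4")

# Column layout of the worked example: 7 states per column in the order
# q1 q2 q3 r1 r2 r3 r4. Columns marked "constrained" realize the class
# plan below; "filler" columns only need a non-uniform query.
_WORKED_COLUMNS: tuple[str, ...] = (
    "AAAGGGG",  # p1  constrained: binary (query A vs reference G)
    "ACGTTTT",  # p2  filler
    "CAGTTAC",  # p3  filler
    "ATGCAGT",  # p4  filler
    "GGGAATT",  # p5  constrained: asymmetric, Q=<0,0,3,0,0,0> R=<2,0,0,2,0,0>
    "TACGGAT",  # p6  filler
    "CGACTGA",  # p7  filler
    "GGGGGAA",  # p8  constrained: noisy (query G shared, r-rank 2)
    "ATCAATC",  # p9  filler
    "GCTTACG",  # p10 filler
    "TGA-ACT",  # p11 filler
    "A-CGGTA",  # p12 filler
    "CCCGGTT",  # p13 constrained: asymmetric (query C vs reference G/T)
    "TCAGCAT",  # p14 filler
    "AAAAAAA",  # p15 constrained: conserved
    "CCCCCCC",  # p16 constrained: conserved
    "GGGGGGG",  # p17 constrained: conserved
    "GTCATGC",  # p18 filler
    "CCCGGCC",  # p19 constrained: noisy; pairs with p20 -> GA,GA,CT,CT vs CA
    "AAAAATT",  # p20 constrained: noisy
    "CATGCTA",  # p21 filler
    "TTACAGC",  # p22 filler
    "TTTTCTC",  # p23 constrained: noisy; CT/AT shared in pairs with p19/p20
    "GACTACG",  # p24 filler
)

#: Classes the constrained columns of the worked example realize.
WORKED_EXAMPLE_CLASSES: Mapping[int, CharClass] = {
    1: CharClass.BINARY,
    5: CharClass.ASYMMETRIC,
    8: CharClass.NOISY,
    13: CharClass.ASYMMETRIC,
    15: CharClass.CONSERVED,
    16: CharClass.CONSERVED,
    17: CharClass.CONSERVED,
    19: CharClass.NOISY,
    20: CharClass.NOISY,
    23: CharClass.NOISY,
}

_WORKED_NEWICK = "((q1,q2,q3)query,(r1,r2,r3,r4)reference);"


def generate_worked_example() -> tuple[Alignment, PhyloTree, GroupPartition]:
    """The deterministic 7-sequence, 24-column worked-example fixture."""
    all_ids = QUERY_IDS + REFERENCE_IDS
    records = {
        sid: "".join(col[row] for col in _WORKED_COLUMNS)
        for row, sid in enumerate(all_ids)
    }
    aln = Alignment(records)
    tree = tree_from_string(_WORKED_NEWICK)
    part = GroupPartition(query_ids=frozenset(QUERY_IDS),
                          reference_ids=frozenset(REFERENCE_IDS))
    return aln, tree, part


_BASES = ("A", "C", "G", "T")
_PLANTABLE = ("A", "C", "G", "T", "-")  # query candidates must avoid N


def _plant_column(cls: CharClass, n_query: int, n_reference: int,
                  rng: random.Random) -> str:
    """One column (query states then reference states) realizing ``cls``.

    Construction follows the set-based definitions: S_Q = distinct query
    states, S_R = distinct reference states; candidate iff |S_Q| = 1 and
    N not in S_Q; binary iff disjoint and |S_R| = 1; asymmetric iff
    disjoint and |S_R| > 1; conserved iff S_R = S_Q; noisy otherwise.
    """
    if cls is CharClass.NON_CANDIDATE:
        if n_query >= 2:
            s, t = rng.sample(_BASES, 2)
            query = [s, t] + [rng.choice(_BASES) for _ in range(n_query - 2)]
        else:
            query = ["N"]  # N in the query always breaks candidacy
        reference = [rng.choice(_BASES) for _ in range(n_reference)]
        return "".join(query + reference)

    s = rng.choice(_PLANTABLE)
    query = [s] * n_query
    others = [b for b in _PLANTABLE if b != s]
    if cls is CharClass.BINARY:
        t = rng.choice(others)
        reference = [t] * n_reference
    elif cls is CharClass.CONSERVED:
        reference = [s] * n_reference
    elif cls is CharClass.ASYMMETRIC:
        if n_reference < 2:
            raise PlanError("asymmetric column needs >= 2 reference sequences")
        t, u = rng.sample(others, 2)
        reference = [t, u] + [rng.choice(others)
                              for _ in range(n_reference - 2)]
    elif cls is CharClass.NOISY:
        if n_reference < 2:
            raise PlanError("noisy column needs >= 2 reference sequences")
        t = rng.choice(others)
        reference = [s, t] + [rng.choice(_PLANTABLE)
                              for _ in range(n_reference - 2)]
    else:  # pragma: no cover - exhaustive over CharClass
        raise PlanError(f"cannot plant class {cls}")
    rng.shuffle(reference)
    return "".join(query + reference)


def generate_random_fixture(
    n_query: int,
    n_reference: int,
    length: int,
    class_plan: Mapping[int, CharClass],
    seed: int,
) -> tuple[Alignment, GroupPartition, dict[int, CharClass]]:
    """Seeded alignment in which each planned 1-based column realizes
    its class; unplanned columns are randomized non-candidates.

    Returns the alignment, the partition, and the expected class of
    every column (planned classes plus NON_CANDIDATE elsewhere).
    """
    if n_query < 1 or n_reference < 1:
        raise PlanError("both groups need at least one sequence")
    bad = [p for p in class_plan if not 1 <= p <= length]
    if bad:
        raise PlanError(f"planned positions outside alignment: {sorted(bad)}")

    rng = random.Random(seed)
    expected: dict[int, CharClass] = {}
    columns: list[str] = []
    for pos in range(1, length + 1):
        cls = class_plan.get(pos, CharClass.NON_CANDIDATE)
        columns.append(_plant_column(cls, n_query, n_reference, rng))
        expected[pos] = cls

    query_ids = tuple(f"q{i}" for i in range(1, n_query + 1))
    reference_ids = tuple(f"r{i}" for i in range(1, n_reference + 1))
    records = {
        sid: "".join(col[row] for col in columns)
        for row, sid in enumerate(query_ids + reference_ids)
    }
    aln = Alignment(records)
    part = GroupPartition(query_ids=frozenset(query_ids),
                          reference_ids=frozenset(reference_ids))
    return aln, part, expected
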
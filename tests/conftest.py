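import random

import pytest

from sigchar import generate_worked_example
from sigchar.alignment import ALPHABET, Alignment, GroupPartition


@pytest.fixture(scope="session")
def worked_example():
    return generate_worked_example()


@pytest.fixture
def worked_aln(worked_example):
    return worked_example[0]


@pytest.fixture
def worked_tree(worked_example):
    return worked_example[1]


@pytest.fixture
def worked_part(worked_example):
    return worked_example[2]


def oracle_classify(query_states: str, reference_states: str) -> str:
    """Set-based brute-force classification of one raw column.

    Independent of the vector-metric implementation: works on the
    distinct-state sets of the raw column symbols.
    """
    s_q = set(query_states)
    s_r = set(reference_states)
    if len(s_q) != 1 or "N" in s_q:
        return "non_candidate"
    if not (s_q & s_r):
        return "binary" if len(s_r) == 1 else "asymmetric"
    if s_r == s_q:
        return "conserved"
    return "noisy"


def make_column_alignment(query_states: str, reference_states: str):
    """Single-column alignment + partition from raw group state strings."""
    records = {}
    for n, c in enumerate(query_states, start=1):
        records[f"q{n}"] = c
    for n, c in enumerate(reference_states, start=1):
        records[f"r{n}"] = c
    aln = Alignment(records)
    part = GroupPartition(
        query_ids=frozenset(k for k in records if k.startswith("q")),
        reference_ids=frozenset(k for k in records if k.startswith("r")))
    return aln, part


def random_column(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(ALPHABET) for _ in range(n))
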
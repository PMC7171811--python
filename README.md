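# sigchar

Detection, ranking and classification of diagnostic signature characters
in nucleotide sequence alignments.

Given a multiple sequence alignment (FASTA) and a partition of its
sequences into a *query* group and a *reference* group (explicit id
lists, or subtree selection on an optional Newick tree), sigchar:

1. represents every alignment column as a pair of **character state
   vectors** — count vectors over the ordered state list
   `⟨A, C, G, T, -, N⟩` — one for each group;
2. ranks all positions by **diagnostic relevance**: discriminative power
   (normalized L1 distance between the two vectors, descending), query
   rank and reference rank (non-zero vector dimensions, ascending);
3. classifies **candidate characters** (positions where the query group
   is uniform in a single non-N state) as *binary*, *asymmetric*,
   *noisy*, or *conserved*; binary and asymmetric candidates
   (discriminative power exactly 1) are **signature characters** that
   separate every query member from every reference member;
4. searches for **combined characters**: pairs of noisy candidate
   positions within a user-chosen k-window whose 36-dimensional pair
   state vectors may become jointly diagnostic;
5. reports a per-column Shannon **entropy profile** of the full
   alignment, marking variable and conserved regions.

Discriminative power is computed in exact rational arithmetic from the
integer counts, so the classification threshold `d = 1` is an exact
integer test, never a float comparison.

## CLI

```sh
sigchar --alignment aln.fasta --query "q1,q2,q3" --k 5 --out results/

# or select groups on a tree (reference defaults to the complement):
sigchar --alignment aln.fasta --tree tree.nwk --query-node cladeA \
        --k 5 --plots --out results/
```

Key flags: `--query`/`--query-node`, `--reference`/`--reference-node`
(default: complement of the query), `--k` (k-window; omit to skip the
combined-character search), `--ambiguity {mask,strict}` (IUPAC
degeneracy codes masked to N, or rejected), `--entropy-include-missing`,
`--plots`, `--log-level`.

Outputs in the `--out` directory: `ranked_table.tsv` (all positions in
relevance order, with metrics, consensus states — non-uniform prevalent
states are marked `*` — class labels and signature flags),
`combined.tsv`, `entropy.tsv`, `signatures.txt`, `run_metadata.json`,
and optional `entropy.png` / `signature_bar.png`.

## Library

```python
from sigchar import (generate_worked_example, rank_alignment,
                     find_combined_characters, entropy_profile)

aln, tree, part = generate_worked_example()   # deterministic fixture
ranked = rank_alignment(aln, part)
pairs = find_combined_characters(aln, part, ranked, k=5)
profile = entropy_profile(aln)
```

`sigchar.fixtures` also provides `generate_random_fixture`, which builds
seeded alignments with planted per-column classes for validation.

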
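"""End-to-end analysis: configuration, execution, result container."""

from __future__ import annotations

import datetime
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .alignment import (
    Alignment,
    GroupPartition,
    PhyloTree,
    read_alignment,
    read_tree,
    resolve_groups,
)
from .classify import RankedTable, rank_alignment
from .combined import CombinedCharacter, find_combined_characters
from .entropy import EntropyProfile, entropy_profile
from .errors import ParameterError


@dataclass(frozen=True)
class AnalysisConfig:
    """All inputs of one analysis run."""

    alignment_path: Path
    query_spec: str
    reference_spec: Optional[str] = None
    tree_path: Optional[Path] = None
    query_is_node: bool = False
    reference_is_node: bool = False
    k_window: Optional[int] = None  # None disables the combined search
    ambiguity_policy: str = "mask"
    entropy_include_missing: bool = False
    output_dir: Path = Path(".")

    def __post_init__(self) -> None:
        if self.k_window is not None and self.k_window < 1:
            raise ParameterError(
                f"k-window must be >= 1, got {self.k_window}")


@dataclass(frozen=True)
class AnalysisResult:
    """Mutually consistent outputs of one run."""

    ranked_table: RankedTable
    signature_positions: tuple[int, ...]
    combined: tuple[CombinedCharacter, ...]
    entropy: EntropyProfile
    run_metadata: dict

    def __post_init__(self) -> None:
        expected = tuple(r.position for r in self.ranked_table.signature_rows())
        assert self.signature_positions == expected, \
            "signature positions inconsistent with ranked table"


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def analyze(
    aln: Alignment,
    part: GroupPartition,
    *,
    k_window: Optional[int] = None,
    entropy_include_missing: bool = False,
    metadata: Optional[dict] = None,
) -> AnalysisResult:
    """Run ranking, classification, combined search and entropy profile
    on in-memory inputs. Deterministic for fixed inputs."""
    ranked = rank_alignment(aln, part)
    combined: tuple[CombinedCharacter, ...] = ()
    if k_window is not None:
        combined = tuple(find_combined_characters(aln, part, ranked, k_window))
    meta = dict(metadata or {})
    meta.setdefault("version", __version__)
    meta.setdefault("parameters", {})
    meta["parameters"].update({
        "k_window": k_window,
        "entropy_include_missing": entropy_include_missing,
        "n_query": len(part.query_ids),
        "n_reference": len(part.reference_ids),
        "alignment_length": aln.length,
        "n_sequences": aln.n_sequences,
    })
    meta.setdefault(
        "timestamp",
        datetime.datetime.now(datetime.timezone.utc).isoformat())
    return AnalysisResult(
        ranked_table=ranked,
        signature_positions=tuple(
            r.position for r in ranked.signature_rows()),
        combined=combined,
        entropy=entropy_profile(
            aln, include_missing=entropy_include_missing),
        run_metadata=meta,
    )


def run_analysis(cfg: AnalysisConfig) -> AnalysisResult:
    """Load inputs per ``cfg``, resolve groups, and run the analysis."""
    aln = read_alignment(cfg.alignment_path, on_ambiguity=cfg.ambiguity_policy)
    tree: Optional[PhyloTree] = None
    if cfg.tree_path is not None:
        tree = read_tree(cfg.tree_path)
    part = resolve_groups(
        aln, cfg.query_spec, cfg.reference_spec, tree,
        query_is_node=cfg.query_is_node,
        reference_is_node=cfg.reference_is_node)
    metadata = {
        "parameters": {
            "alignment_path": str(cfg.alignment_path),
            "tree_path": str(cfg.tree_path) if cfg.tree_path else None,
            "query_spec": cfg.query_spec,
            "reference_spec": cfg.reference_spec,
            "ambiguity_policy": cfg.ambiguity_policy,
        },
        "input_digests": {
            "alignment": _digest(Path(cfg.alignment_path)),
            **({"tree": _digest(Path(cfg.tree_path))}
               if cfg.tree_path else {}),
        },
    }
    return analyze(
        aln, part,
        k_window=cfg.k_window,
        entropy_include_missing=cfg.entropy_include_missing,
        metadata=metadata,
    )
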
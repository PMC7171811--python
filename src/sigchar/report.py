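"""Result serialization: TSV tables, signature summary, metadata sidecar,
optional plots.

Files written by :func:`write_reports`:

- ``ranked_table.tsv`` — every alignment position in relevance order
- ``combined.tsv``     — classified combined characters (may be empty)
- ``entropy.tsv``      — per-position entropy in bits
- ``signatures.txt``   — plain-text summary of signature characters
- ``run_metadata.json``— parameters, input digests, timestamp, version

d-power values are printed with 4 decimals. Plot images (signature bar,
entropy profile) are optional and never required by tests.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING

from .classify import CharClass, PositionMetrics, RankedTable, ranking_key
from .errors import SigcharError

if TYPE_CHECKING:  # pragma: no cover
    from .analysis import AnalysisResult

RANKED_COLUMNS = ("rank", "position", "d_power", "q_rank", "r_rank",
                  "query_state", "reference_state", "class",
                  "is_signature", "ref_has_missing")

COMBINED_COLUMNS = ("rank", "i", "j", "d_power", "q_rank", "r_rank",
                    "query_pair", "reference_pair", "class",
                    "is_signature")


def _fmt_d(d) -> str:
    return f"{float(d):.4f}"


def _state_repr(cs) -> str:
    # prevalent (non-uniform) states are marked to distinguish them from
    # uniform ones in the table
    return cs.state if cs.is_uniform else f"{cs.state}*"


def write_ranked_table(ranked: RankedTable, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(RANKED_COLUMNS) + "\n")
        for rank, row in enumerate(ranked.rows, start=1):
            fh.write("\t".join((
                str(rank), str(row.position), _fmt_d(row.d_power),
                str(row.q_rank), str(row.r_rank),
                _state_repr(row.query_state),
                _state_repr(row.reference_state),
                row.char_class.value,
                str(row.is_signature).lower(),
                str(row.ref_has_missing).lower())) + "\n")


def read_ranked_table(path: Path) -> list[dict]:
    """Parse ``ranked_table.tsv`` back into row dicts (round-trip aid)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != RANKED_COLUMNS:
            raise SigcharError(f"unexpected ranked-table header in {path}")
        rows = []
        for line in fh:
            vals = line.rstrip("\n").split("\t")
            rec = dict(zip(header, vals))
            rec["rank"] = int(rec["rank"])
            rec["position"] = int(rec["position"])
            rec["d_power"] = float(rec["d_power"])
            rec["q_rank"] = int(rec["q_rank"])
            rec["r_rank"] = int(rec["r_rank"])
            rows.append(rec)
    return rows


def write_combined_table(combined, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(COMBINED_COLUMNS) + "\n")
        for rank, c in enumerate(combined, start=1):
            fh.write("\t".join((
                str(rank), str(c.i), str(c.j), _fmt_d(c.d_power),
                str(c.q_rank), str(c.r_rank),
                _state_repr(c.query_pair), _state_repr(c.reference_pair),
                c.char_class.value,
                str(c.is_signature).lower())) + "\n")


def write_entropy_table(profile, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tentropy_bits\n")
        for pos, h in enumerate(profile.values, start=1):
            fh.write(f"{pos}\t{h:.6f}\n")


def write_signatures(res: "AnalysisResult", path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# signature characters (d-power = 1)\n")
        for row in res.ranked_table.signature_rows():
            fh.write(f"position {row.position}\t{row.char_class.value}\t"
                     f"query={_state_repr(row.query_state)}\t"
                     f"reference={_state_repr(row.reference_state)}\n")
        diagnostic_pairs = [c for c in res.combined if c.is_signature]
        fh.write("# combined signature characters\n")
        for c in diagnostic_pairs:
            fh.write(f"positions ({c.i},{c.j})\t{c.char_class.value}\t"
                     f"query={_state_repr(c.query_pair)}\t"
                     f"reference={_state_repr(c.reference_pair)}\n")


def write_reports(res: "AnalysisResult", out_dir: Path,
                  *, plots: bool = False) -> dict[str, Path]:
    """Write all report files into ``out_dir``; returns name -> path."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise SigcharError(f"cannot create output dir {out_dir}: {exc}")
    files = {
        "ranked_table": out_dir / "ranked_table.tsv",
        "combined": out_dir / "combined.tsv",
        "entropy": out_dir / "entropy.tsv",
        "signatures": out_dir / "signatures.txt",
        "run_metadata": out_dir / "run_metadata.json",
    }
    write_ranked_table(res.ranked_table, files["ranked_table"])
    write_combined_table(res.combined, files["combined"])
    write_entropy_table(res.entropy, files["entropy"])
    write_signatures(res, files["signatures"])
    with open(files["run_metadata"], "w") as fh:
        json.dump(res.run_metadata, fh, indent=2, default=str)
        fh.write("\n")
    if plots:
        files.update(_write_plots(res, out_dir))
    return files


def _write_plots(res: "AnalysisResult", out_dir: Path) -> dict[str, Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(res.entropy.values)
    files = {}

    fig, ax = plt.subplots(figsize=(max(6, n / 10), 2.5))
    ax.plot(range(1, n + 1), res.entropy.values, lw=0.9, color="#305080")
    ax.set_xlabel("alignment position")
    ax.set_ylabel("entropy (bits)")
    ax.set_xlim(1, n)
    fig.tight_layout()
    files["entropy_plot"] = out_dir / "entropy.png"
    fig.savefig(files["entropy_plot"], dpi=150)
    plt.close(fig)

    colors = {CharClass.BINARY: "#1a9850", CharClass.ASYMMETRIC: "#66bd63",
              CharClass.NOISY: "#fdae61"}
    fig, ax = plt.subplots(figsize=(max(6, n / 10), 1.4))
    for row in res.ranked_table.rows:
        color = colors.get(row.char_class)
        if color:
            ax.axvline(row.position, color=color, lw=2)
    ax.set_xlim(0.5, n + 0.5)
    ax.set_yticks([])
    ax.set_xlabel("alignment position")
    fig.tight_layout()
    files["signature_bar"] = out_dir / "signature_bar.png"
    fig.savefig(files["signature_bar"], dpi=150)
    plt.close(fig)
    return files
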
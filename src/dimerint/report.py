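"""Rendering of energy tables, FRET summaries and geometry tables.

Energies print at 2 decimals and percentages at 1 decimal, matching the
conventions of the published table this layout mirrors.  Subtotals are
computed in full precision and then rounded — never summed from rounded
rows — so a rendered subtotal may differ from the sum of the rendered rows
by up to 0.02 kcal/mol; when it does, a rounding note is appended to the
table.  A full-precision JSON companion is always written next to the TSV.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .energetics import EnergyDecomposition, EnergyTerm
from .fret import FretSummary

__all__ = ["RunManifest", "render_energy_table", "render_fret_summary"]


@dataclass
class RunManifest:
    """Reproducibility record attached to every rendered table."""

    tool: str = "dimerint"
    version: str = "0.1.0"
    seeds: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    input_checksums: dict = field(default_factory=dict)

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.input_checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "tool": self.tool,
                    "version": self.version,
                    "seeds": self.seeds,
                    "config": self.config,
                    "input_checksums": self.input_checksums,
                },
                fh,
                sort_keys=True,
            )


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def _term_cells(term: EnergyTerm | None) -> list[str]:
    if term is None:
        return ["", "", ""]
    return [_fmt(term.coulombic), _fmt(term.vdw), _fmt(term.total())]


def render_energy_table(
    decomp: EnergyDecomposition,
    path: str | Path,
    manifest: RunManifest | None = None,
) -> None:
    """Write the decomposition as a TSV table plus a full-precision JSON
    companion (``<path>.full.json``).

    Requires a summarized decomposition (subtotals and total filled).
    """
    if decomp.grand_total is None:
        raise ValueError("decomposition must be summarized before rendering")
    path = Path(path)
    lines = ["\t".join(["Interaction energies", "Coulombic", "VDW", "Total"])]
    for row in decomp.protomer_rows:
        lines.append("\t".join([row.residue_label, *_term_cells(row.term)]))
    lines.append("\t".join(["Subtotal", *_term_cells(decomp.protomer_subtotal)]))
    lines.append("\t".join(["Cholesterol A, Protomer B", *_term_cells(decomp.chol_a_vs_b)]))
    lines.append("\t".join(["Cholesterol B, Protomer A", *_term_cells(decomp.chol_b_vs_a)]))
    lines.append("\t".join(["Subtotal", *_term_cells(decomp.chol_subtotal)]))
    lines.append("\t".join(["Total", *_term_cells(decomp.grand_total)]))
    pct = decomp.chol_fraction_percent
    pct_str = "n/a" if pct is None or pct != pct else f"{pct:.1f}"
    lines.append(f"Cholesterol contribution (%)\t{pct_str}")

    note = _rounding_note(decomp)
    if note:
        lines.append(f"# {note}")
    path.write_text("\n".join(lines) + "\n")

    full = {
        "rows": [
            {
                "label": r.residue_label,
                "coulombic": r.term.coulombic,
                "vdw": r.term.vdw,
                "total": r.term.total(),
            }
            for r in decomp.protomer_rows
        ],
        "chol_a_vs_b": _term_dict(decomp.chol_a_vs_b),
        "chol_b_vs_a": _term_dict(decomp.chol_b_vs_a),
        "palm_a_vs_b": _term_dict(decomp.palm_a_vs_b),
        "palm_b_vs_a": _term_dict(decomp.palm_b_vs_a),
        "protomer_subtotal": _term_dict(decomp.protomer_subtotal),
        "chol_subtotal": _term_dict(decomp.chol_subtotal),
        "grand_total": _term_dict(decomp.grand_total),
        "chol_fraction_percent": decomp.chol_fraction_percent,
    }
    Path(str(path) + ".full.json").write_text(json.dumps(full, indent=1))
    if manifest is not None:
        manifest.write(Path(str(path) + ".manifest.yaml"))


def _term_dict(term: EnergyTerm | None) -> dict | None:
    if term is None:
        return None
    return {"coulombic": term.coulombic, "vdw": term.vdw, "total": term.total()}


def _rounding_note(decomp: EnergyDecomposition) -> str | None:
    """Note emitted when the rounded subtotal differs from the sum of
    rounded rows (a rounding artifact, bounded by 0.02 kcal/mol here)."""
    if not decomp.protomer_rows or decomp.protomer_subtotal is None:
        return None
    rounded_sum = sum(round(r.term.total(), 2) for r in decomp.protomer_rows)
    printed = round(decomp.protomer_subtotal.total(), 2)
    if abs(rounded_sum - printed) > 0.005:
        return (
            f"note: subtotal {printed:.2f} is rounded from full precision; the "
            f"rounded rows sum to {rounded_sum:.2f}"
        )
    return None


def render_fret_summary(
    summaries: Mapping[str, FretSummary],
    path: str | Path,
    manifest: RunManifest | None = None,
) -> None:
    """TSV of condition, mean NFRET, SD, counts and validity flag, one row
    per condition in input order."""
    if not summaries:
        raise ValueError("no summaries to render")
    path = Path(path)
    lines = ["condition\tmean_nfret\tsd\tn_cells\tn_rois_per_cell\tvalidity"]
    for cond, s in summaries.items():
        flag = "ok" if s.valid else "warn"
        lines.append(
            f"{cond}\t{s.mean_nfret:.4f}\t{s.sd:.4f}\t{s.n_cells}\t{s.n_rois_per_cell}\t{flag}"
        )
    path.write_text("\n".join(lines) + "\n")
    if manifest is not None:
        manifest.write(Path(str(path) + ".manifest.yaml"))
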
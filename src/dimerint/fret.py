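"""Sensitized-emission FRET normalization and pixel colocalization.

Three-cube FRET measures ROI intensities in three filter sets: the FRET
channel (donor excitation / acceptor emission, ``i_fret``), the donor
channel (``i_cfp``) and the acceptor channel (``i_yfp``).  Bleed-through
coefficients come from single-fluorophore controls (CoA = I_FRET/I_CFP in
donor-only cells; CoB = I_FRET/I_YFP in acceptor-only cells), and the
normalized net FRET of an ROI is

    NFRET = (I_FRET − CoA·I_CFP − CoB·I_YFP) / √(I_CFP · I_YFP)

The √(I_CFP·I_YFP) denominator removes the dependence on the expression
levels of the two fluorophores, so NFRET is invariant under uniform
intensity rescaling.

Aggregation follows the source protocol: ≥ 20 membrane ROIs per cell and
≥ 12 cells per condition; the summary reports mean and SD (not SEM) across
all ROIs and warns when the counts fall below those thresholds.

Pixel colocalization of two channels is 2·N_yellow/(N_red + N_green), where
the N are the pixel counts above a per-channel intensity threshold and
"yellow" pixels exceed it in both channels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RoiIntensity",
    "BleedthroughCoefficients",
    "ColocalizationCounts",
    "FretSummary",
    "estimate_bleedthrough",
    "normalized_net_fret",
    "summarize_fret",
    "pipeline_standard_error",
    "colocalization_index",
    "read_roi_table",
]

MIN_ROIS_PER_CELL = 20
MIN_CELLS = 12


@dataclass(frozen=True)
class RoiIntensity:
    """Three-channel intensities (arbitrary units) of one membrane ROI."""

    i_fret: float
    i_cfp: float
    i_yfp: float
    cell_id: str = ""

    def __post_init__(self) -> None:
        for name in ("i_fret", "i_cfp", "i_yfp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class BleedthroughCoefficients:
    """Donor (CoA) and acceptor (CoB) bleed-through into the FRET channel.

    When estimated from controls, ``n_*`` and ``sd_*`` record the number of
    ROIs used and the spread of the per-ROI ratios.
    """

    co_a: float
    co_b: float
    n_a: int = 0
    n_b: int = 0
    sd_a: float = math.nan
    sd_b: float = math.nan


@dataclass(frozen=True)
class ColocalizationCounts:
    """Above-threshold pixel counts for the two channels and their overlap."""

    n_red: int
    n_green: int
    n_yellow: int
    threshold: float = math.nan

    def __post_init__(self) -> None:
        if min(self.n_red, self.n_green, self.n_yellow) < 0:
            raise ValueError("pixel counts must be >= 0")
        if self.n_yellow > min(self.n_red, self.n_green):
            raise ValueError(
                "n_yellow cannot exceed min(n_red, n_green): overlap pixels are "
                "above threshold in both channels"
            )


@dataclass(frozen=True)
class FretSummary:
    mean_nfret: float
    sd: float
    n_cells: int
    n_rois_per_cell: int  # minimum across cells
    valid: bool


def _ratios(rois: Sequence[RoiIntensity], denom_attr: str) -> np.ndarray:
    vals = []
    for roi in rois:
        denom = getattr(roi, denom_attr)
        if denom <= 0:
            warnings.warn(
                f"ROI {roi.cell_id!r}: zero {denom_attr}; excluded from "
                "bleed-through estimate"
            )
            continue
        vals.append(roi.i_fret / denom)
    if not vals:
        raise ValueError(f"no usable ROIs (all had zero {denom_attr})")
    return np.asarray(vals)


def estimate_bleedthrough(
    donor_only: Sequence[RoiIntensity],
    acceptor_only: Sequence[RoiIntensity],
) -> BleedthroughCoefficients:
    """CoA/CoB as the mean I_FRET/I_CFP (donor-only) and I_FRET/I_YFP
    (acceptor-only) ratios across control ROIs."""
    if not donor_only or not acceptor_only:
        raise ValueError("both control collections must be non-empty")
    ra = _ratios(donor_only, "i_cfp")
    rb = _ratios(acceptor_only, "i_yfp")
    return BleedthroughCoefficients(
        co_a=float(ra.mean()),
        co_b=float(rb.mean()),
        n_a=len(ra),
        n_b=len(rb),
        sd_a=float(ra.std(ddof=1)) if len(ra) > 1 else math.nan,
        sd_b=float(rb.std(ddof=1)) if len(rb) > 1 else math.nan,
    )


def normalized_net_fret(
    roi: RoiIntensity,
    co: BleedthroughCoefficients,
    formula: str = "standard",
) -> float:
    """Normalized net FRET of one ROI.

    ``formula="standard"`` is the three-cube form given in the module
    docstring.  ``formula="as_printed"`` evaluates the literal published
    variant (CoA·I_CFP − CoB·I_YFP)/√(I_CFP·I_YFP), which omits the measured
    FRET-channel term and is provided for audit only — it is not a FRET
    estimate.
    """
    denom_sq = roi.i_cfp * roi.i_yfp
    if denom_sq <= 0:
        raise ValueError("i_cfp * i_yfp must be > 0 for normalization")
    denom = math.sqrt(denom_sq)
    if formula == "standard":
        return (roi.i_fret - co.co_a * roi.i_cfp - co.co_b * roi.i_yfp) / denom
    if formula == "as_printed":
        return (co.co_a * roi.i_cfp - co.co_b * roi.i_yfp) / denom
    raise ValueError(f"unknown formula {formula!r}")


def summarize_fret(
    rois: Sequence[RoiIntensity] | Mapping[str, Sequence[RoiIntensity]],
    co: BleedthroughCoefficients,
    formula: str = "standard",
) -> FretSummary:
    """Mean ± SD of per-ROI NFRET across all ROIs of all cells.

    Accepts either a flat ROI sequence (grouped by each ROI's ``cell_id``)
    or an explicit cell_id → ROIs mapping.  Warns when the sampling falls
    below the protocol's ≥ 20 ROIs/cell and ≥ 12 cells thresholds.
    """
    if isinstance(rois, Mapping):
        groups = {k: list(v) for k, v in rois.items()}
    else:
        groups = {}
        for roi in rois:
            groups.setdefault(roi.cell_id, []).append(roi)
    groups = {k: v for k, v in groups.items() if v}
    if not groups:
        raise ValueError("no ROIs")
    values = np.array(
        [normalized_net_fret(r, co, formula) for cell in groups.values() for r in cell]
    )
    n_cells = len(groups)
    min_rois = min(len(v) for v in groups.values())
    valid = n_cells >= MIN_CELLS and min_rois >= MIN_ROIS_PER_CELL
    if not valid:
        warnings.warn(
            f"below protocol thresholds: {n_cells} cells "
            f"(need >= {MIN_CELLS}), min {min_rois} ROIs/cell "
            f"(need >= {MIN_ROIS_PER_CELL})"
        )
    return FretSummary(
        mean_nfret=float(values.mean()),
        sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        n_cells=n_cells,
        n_rois_per_cell=min_rois,
        valid=valid,
    )


def pipeline_standard_error(
    summary: FretSummary,
    co: BleedthroughCoefficients,
    rois: Sequence[RoiIntensity] | Mapping[str, Sequence[RoiIntensity]],
) -> float:
    """Standard error of the pipeline's mean NFRET.

    The ROI-to-ROI scatter term sd/√N alone understates the uncertainty:
    CoA and CoB are themselves estimated from finite control samples, and an
    error ΔCoA shifts every ROI's NFRET coherently by
    −ΔCoA·⟨I_CFP/√(I_CFP·I_YFP)⟩ (similarly for CoB).  Propagating both
    control uncertainties gives

        SE² = sd²/N + (sd_A²/n_A)·⟨√(I_CFP/I_YFP)⟩² + (sd_B²/n_B)·⟨√(I_YFP/I_CFP)⟩²

    Control terms with unknown spread (sd NaN) contribute zero.
    """
    if isinstance(rois, Mapping):
        flat = [r for cell in rois.values() for r in cell]
    else:
        flat = list(rois)
    n = len(flat)
    m_a = float(np.mean([math.sqrt(r.i_cfp / r.i_yfp) for r in flat]))
    m_b = float(np.mean([math.sqrt(r.i_yfp / r.i_cfp) for r in flat]))
    var = summary.sd**2 / n
    if co.n_a > 1 and math.isfinite(co.sd_a):
        var += (co.sd_a**2 / co.n_a) * m_a**2
    if co.n_b > 1 and math.isfinite(co.sd_b):
        var += (co.sd_b**2 / co.n_b) * m_b**2
    return math.sqrt(var)


def colocalization_index(counts: ColocalizationCounts) -> float:
    """2·N_yellow/(N_red + N_green) ∈ [0, 1]."""
    denom = counts.n_red + counts.n_green
    if denom == 0:
        raise ValueError("n_red + n_green must be > 0")
    return 2.0 * counts.n_yellow / denom


def read_roi_table(path: str | Path) -> dict[str, list[RoiIntensity]]:
    """Read a TSV/CSV ROI intensity table (columns cell_id, i_fret, i_cfp,
    i_yfp, optional condition) into condition → ROI list ('' if absent)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"cell_id", "i_fret", "i_cfp", "i_yfp"}
    if not required.issubset(df.columns):
        raise ValueError(f"ROI table must have columns {sorted(required)}")
    out: dict[str, list[RoiIntensity]] = {}
    for row in df.itertuples(index=False):
        cond = str(getattr(row, "condition", ""))
        out.setdefault(cond, []).append(
            RoiIntensity(
                i_fret=float(row.i_fret),
                i_cfp=float(row.i_cfp),
                i_yfp=float(row.i_yfp),
                cell_id=str(row.cell_id),
            )
        )
    return out
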
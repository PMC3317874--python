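"""Synthetic fixtures: kinked helices, parameterized toy dimers, FRET ROI
tables, and the packaged reference interface-energy table.

Every generator is a pure function of its spec and seed and emits its
ground-truth construction parameters alongside the data, so recovery tests
can compare estimates against truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .cm import HelixConformation, build_helix
from .energetics import EnergyDecomposition, EnergyTableRow, EnergyTerm
from .fret import RoiIntensity
from .geometry import fit_axis, _radial, _rotation_matrix
from .structures import AtomRecord, DimerComplex, Protomer, Residue

__all__ = [
    "DimerFixtureSpec",
    "FretGeneratorSpec",
    "make_kinked_helix",
    "make_dimer_fixture",
    "make_fret_rois",
    "load_reference_interface_energies",
]


# --------------------------------------------------------------------------
# Kinked helices
# --------------------------------------------------------------------------

def make_kinked_helix(
    sequence: str,
    flex_residue: int,
    bend_deg: float,
    wobble_deg: float,
    seed: int = 0,
) -> HelixConformation:
    """Ideal helix with a rigid-body kink of known bend and wobble.

    All atoms of residues after ``flex_residue`` (0-based) are rotated by
    ``bend_deg`` about an axis through that residue's Cα, oriented so that
    the post-segment axis tilts in the azimuthal direction ``wobble_deg``
    (measured from the flex residue's radial direction, counterclockwise
    looking N→C).  The construction parameters are stored on the returned
    object as ``ground_truth``.  ``seed`` is accepted for interface
    uniformity; the construction is noise-free and deterministic.
    """
    if not (0.0 <= bend_deg <= 90.0):
        raise ValueError("bend_deg must be in [0, 90]")
    n = len(sequence)
    if flex_residue < 5 or flex_residue > n - 6:
        raise ValueError("flex residue too close to the termini")
    helix = build_helix(sequence)
    if bend_deg == 0.0:
        helix.ground_truth = {"bend_deg": 0.0, "wobble_deg": wobble_deg}  # type: ignore[attr-defined]
        return helix

    ca = helix.ca_coords
    axis, center = fit_axis(ca)  # exact for the ideal helix
    hinge = ca[flex_residue].copy()
    r0 = _radial(hinge, axis, center)
    r0 /= np.linalg.norm(r0)
    # tilt direction d = r0 rotated by wobble about the axis;
    # rotating about u = axis × d tilts the post axis toward d
    d = _rotation_matrix(axis, math.radians(wobble_deg)) @ r0
    u = np.cross(axis, d)
    rot = _rotation_matrix(u, math.radians(bend_deg))
    coords = helix.coords.copy()
    for i in range(flex_residue + 1, n):
        coords[i] = hinge + (coords[i] - hinge) @ rot.T
    kinked = helix.copy()
    kinked.coords = coords
    kinked.coords_from_internal = False
    kinked.ground_truth = {"bend_deg": bend_deg, "wobble_deg": wobble_deg}  # type: ignore[attr-defined]
    return kinked


# --------------------------------------------------------------------------
# Toy dimers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DimerFixtureSpec:
    """Two parallel toy protomers at a given separation, with declared
    nonbonded parameters and optional single-group cholesterol proxies.

    ``charge_scheme``: "zero", "alternating" (±charge_magnitude down the
    chain) or "random" (uniform in ±charge_magnitude, seeded).
    ``lj_scheme``: "zero" or "uniform" (every atom gets lj_A/lj_C).
    """

    n_residues_per_protomer: int = 5
    separation: float = 6.0
    charge_scheme: str = "zero"
    lj_scheme: str = "uniform"
    charge_magnitude: float = 0.2
    lj_A: float = 1.0e5
    lj_C: float = 5.0e2
    n_cholesterol: int = 0
    atoms_per_residue: int = 3
    spacing: float = 3.0
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.separation <= 0:
            raise ValueError("separation must be > 0")
        if not 0 <= self.n_cholesterol <= 2:
            raise ValueError("n_cholesterol must be 0-2")
        if self.charge_scheme not in ("zero", "alternating", "random"):
            raise ValueError(f"unknown charge_scheme {self.charge_scheme!r}")
        if self.lj_scheme not in ("zero", "uniform"):
            raise ValueError(f"unknown lj_scheme {self.lj_scheme!r}")


def _toy_charge(spec: DimerFixtureSpec, index: int, rng: np.random.Generator) -> float:
    if spec.charge_scheme == "zero":
        return 0.0
    if spec.charge_scheme == "alternating":
        return spec.charge_magnitude * (1 if index % 2 == 0 else -1)
    return float(rng.uniform(-spec.charge_magnitude, spec.charge_magnitude))


def make_dimer_fixture(spec: DimerFixtureSpec) -> DimerComplex:
    """Build a fully parameterized toy dimer.

    Protomer A runs along z at x = 0, protomer B at x = separation; residues
    are ``spacing`` Å apart with ``atoms_per_residue`` atoms in a small local
    cluster (optionally jittered, seeded).  Residues carry sequential BW
    positions "4.38", "4.39", ... so the decomposition can address them.
    The cholesterol proxies are rigid 3-site uncharged Lennard-Jones groups
    placed in the inter-protomer gap, one tagged per protomer.
    """
    rng = np.random.default_rng(spec.seed)
    offsets = np.array([[0.0, 0.0, 0.0], [0.0, 0.6, 0.4], [0.0, -0.6, 0.4],
                        [0.4, 0.0, -0.5], [-0.4, 0.3, 0.3]])[: spec.atoms_per_residue]

    def protomer(chain: str, x0: float) -> Protomer:
        residues = []
        atom_index = 0
        for i in range(spec.n_residues_per_protomer):
            base = np.array([x0, 0.0, i * spec.spacing])
            atoms = []
            for j in range(spec.atoms_per_residue):
                pos = base + offsets[j]
                if spec.jitter > 0:
                    pos = pos + rng.normal(scale=spec.jitter, size=3)
                atoms.append(
                    AtomRecord(
                        atom_name=f"X{j+1}",
                        element="C",
                        coords=pos,
                        charge_q=_toy_charge(spec, atom_index, rng),
                        lj_A=0.0 if spec.lj_scheme == "zero" else spec.lj_A,
                        lj_C=0.0 if spec.lj_scheme == "zero" else spec.lj_C,
                    )
                )
                atom_index += 1
            residues.append(
                Residue(
                    seq_number=i + 1,
                    aa_code="ALA",
                    atoms=atoms,
                    bw_position=f"4.{38 + i}",
                )
            )
        return Protomer(chain_id=chain, residues=residues)

    prot_a = protomer("A", 0.0)
    prot_b = protomer("B", spec.separation)

    ligands: list[Residue] = []
    chol_sites = np.array([[0.0, 0.0, 0.0], [0.0, 0.8, 0.0], [0.0, 0.0, 0.8]])
    z_mid = 0.5 * (spec.n_residues_per_protomer - 1) * spec.spacing
    for k in range(spec.n_cholesterol):
        tag = "CHOL_A" if k == 0 else "CHOL_B"
        x = spec.separation * (1 + k) / 3.0
        atoms = [
            AtomRecord(
                atom_name=f"S{j+1}", element="C", coords=np.array([x, 0.0, z_mid]) + s,
                charge_q=0.0,
                lj_A=0.0 if spec.lj_scheme == "zero" else spec.lj_A,
                lj_C=0.0 if spec.lj_scheme == "zero" else spec.lj_C,
            )
            for j, s in enumerate(chol_sites)
        ]
        ligands.append(
            Residue(
                seq_number=1000 + k, aa_code="CLR", atoms=atoms,
                is_ligand=True, ligand_tag=tag,
            )
        )
    return DimerComplex(protomer_a=prot_a, protomer_b=prot_b, ligands=ligands)


# --------------------------------------------------------------------------
# FRET ROI tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FretGeneratorSpec:
    """Emulates the statistical structure of membrane-ROI FRET data.

    Channel intensities are lognormal around ``intensity_scale`` (strictly
    positive, realistic coefficient of variation); the FRET channel is the
    bleed-through sum plus ``true_nfret``·√(I_CFP·I_YFP), then multiplicative
    noise with CV ``noise_cv``.  Defaults mirror the study conditions: CoA ≈
    0.30-ish bleed-through magnitudes, 12 cells × 20 membrane ROIs.
    """

    true_nfret: float = 0.49
    co_a: float = 0.30
    co_b: float = 0.15
    intensity_scale: float = 1000.0
    intensity_cv: float = 0.30
    noise_cv: float = 0.05
    n_cells: int = 12
    n_rois_per_cell: int = 20
    n_control_rois: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def _lognormal(rng: np.random.Generator, scale: float, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.full(size, scale)
    sigma2 = math.log(1 + cv**2)
    mu = math.log(scale) - sigma2 / 2
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def make_fret_rois(
    spec: FretGeneratorSpec,
) -> tuple[dict[str, list[RoiIntensity]], list[RoiIntensity], list[RoiIntensity]]:
    """Generate (experimental ROIs by cell, donor-only controls,
    acceptor-only controls); deterministic for a fixed spec."""
    rng = np.random.default_rng(spec.seed)
    cells: dict[str, list[RoiIntensity]] = {}
    for c in range(spec.n_cells):
        cid = f"cell{c:03d}"
        n = spec.n_rois_per_cell
        i_cfp = _lognormal(rng, spec.intensity_scale, spec.intensity_cv, n)
        i_yfp = _lognormal(rng, spec.intensity_scale, spec.intensity_cv, n)
        clean = (
            spec.co_a * i_cfp + spec.co_b * i_yfp
            + spec.true_nfret * np.sqrt(i_cfp * i_yfp)
        )
        noise = rng.normal(loc=1.0, scale=spec.noise_cv, size=n) if spec.noise_cv else 1.0
        i_fret = np.maximum(clean * noise, 0.0)
        cells[cid] = [
            RoiIntensity(i_fret=float(f), i_cfp=float(cch), i_yfp=float(y), cell_id=cid)
            for f, cch, y in zip(i_fret, i_cfp, i_yfp)
        ]
    m = spec.n_control_rois
    d_cfp = _lognormal(rng, spec.intensity_scale, spec.intensity_cv, m)
    d_noise = rng.normal(1.0, spec.noise_cv, m) if spec.noise_cv else 1.0
    donor_only = [
        RoiIntensity(i_fret=float(max(spec.co_a * c * nz, 0.0)), i_cfp=float(c),
                     i_yfp=0.0, cell_id="donor_ctrl")
        for c, nz in zip(d_cfp, np.atleast_1d(d_noise))
    ]
    a_yfp = _lognormal(rng, spec.intensity_scale, spec.intensity_cv, m)
    a_noise = rng.normal(1.0, spec.noise_cv, m) if spec.noise_cv else 1.0
    acceptor_only = [
        RoiIntensity(i_fret=float(max(spec.co_b * y * nz, 0.0)), i_cfp=0.0,
                     i_yfp=float(y), cell_id="acceptor_ctrl")
        for y, nz in zip(a_yfp, np.atleast_1d(a_noise))
    ]
    return cells, donor_only, acceptor_only


def rois_to_frame(cells: dict[str, list[RoiIntensity]], condition: str = "") -> pd.DataFrame:
    rows = [
        {"cell_id": r.cell_id, "roi_id": i, "i_fret": r.i_fret, "i_cfp": r.i_cfp,
         "i_yfp": r.i_yfp, "condition": condition}
        for cell in cells.values() for i, r in enumerate(cell)
    ]
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Reference interface-energy table
# --------------------------------------------------------------------------

def load_reference_interface_energies() -> EnergyDecomposition:
    """Load the packaged reference interface-energy table (the published
    per-residue decomposition of the palmitoylated μ-opioid receptor
    homodimer/cholesterol model).

    Returns a fresh :class:`EnergyDecomposition` with the 16 per-residue rows
    (T4.38 … P4.59), the two cholesterol cross terms and the ingested
    protomer subtotal; the remaining subtotals/total/percentage are left for
    :func:`dimerint.energetics.summarize_table`.  Each transcribed term
    carries its published rounded Total as an override (see
    :class:`dimerint.energetics.EnergyTerm`).  The rows are immutable; every
    call returns an independent object.
    """
    with resources.files("dimerint.data").joinpath(
        "reference_interface_energies.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    decomp = EnergyDecomposition()
    for rec in df.itertuples(index=False):
        term = EnergyTerm(
            coulombic=float(rec.coulombic),
            vdw=float(rec.vdw),
            total_override=float(rec.total),
        )
        if rec.section == "row":
            decomp.protomer_rows.append(
                EnergyTableRow(residue_label=str(rec.label), term=term)
            )
        elif rec.section == "chol_a_vs_b":
            decomp.chol_a_vs_b = term
        elif rec.section == "chol_b_vs_a":
            decomp.chol_b_vs_a = term
        elif rec.section == "protomer_subtotal":
            decomp.protomer_subtotal = term
        else:
            raise ValueError(f"unknown section {rec.section!r} in fixture")
    if len(decomp.protomer_rows) != 16:
        raise ValueError("fixture must contain 16 per-residue rows")
    decomp.protomer_rows = list(decomp.protomer_rows)
    return decomp
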
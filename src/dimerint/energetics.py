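"""Residue-level pairwise nonbonded interface-energy decomposition.

The interaction energy between two atom groups *a* and *b* is

    ΔE_ab = Σ_i Σ_j  k·q_i·q_j/(ε(r_ij)·r_ij)  +  A_ij/r_ij¹² − C_ij/r_ij⁶

with the OPLS geometric combining rules A_ij = √(A_ii·A_jj),
C_ij = √(C_ii·C_jj), and k = 332.0636 kcal·Å/(mol·e²).  In the default
distance-dependent dielectric mode ε(r) = ε₀·r, so the Coulomb term falls
off as 1/r².

The dimer-interface decomposition evaluates each listed interface residue of
protomer A against every residue of protomer B whose minimum interatomic
distance lies within a cutoff radius (default 7.0 Å, boundary inclusive),
plus the two cholesterol cross terms (cholesterol A vs protomer B,
cholesterol B vs protomer A).  Cholesterol–cholesterol and
palmitoyl–palmitoyl pairs are never summed; palmitoyl–opposite-protomer
terms are computed but reported separately and excluded from the grand
total.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .structures import DimerComplex, Protomer, Residue, AtomRecord

__all__ = [
    "COULOMB_K",
    "EnergyTerm",
    "EnergyTableRow",
    "EnergyDecomposition",
    "EnergyOptions",
    "pair_energy",
    "residues_within_radius",
    "residue_vs_protomer_energy",
    "decompose_interface",
    "summarize_table",
]

#: Electrostatic conversion constant, kcal·Å/(mol·e²).
COULOMB_K = 332.0636


@dataclass(frozen=True)
class EnergyTerm:
    """Coulombic + van der Waals energy pair, kcal/mol.

    ``total_override`` exists only for transcribed published tables whose
    printed Total column was rounded from higher precision and therefore may
    differ from the sum of the printed rounded Coulombic and VDW cells by
    0.01 kcal/mol.  Computed terms never set it, and for them
    ``total() == coulombic + vdw`` exactly.
    """

    coulombic: float
    vdw: float
    total_override: float | None = None

    def total(self) -> float:
        if self.total_override is not None:
            return self.total_override
        return self.coulombic + self.vdw

    def __add__(self, other: "EnergyTerm") -> "EnergyTerm":
        override = None
        if self.total_override is not None or other.total_override is not None:
            override = self.total() + other.total()
        return EnergyTerm(self.coulombic + other.coulombic, self.vdw + other.vdw, override)

    @staticmethod
    def zero() -> "EnergyTerm":
        return EnergyTerm(0.0, 0.0)


@dataclass(frozen=True)
class EnergyTableRow:
    residue_label: str  # BW style, e.g. "I4.44"
    term: EnergyTerm


@dataclass
class EnergyDecomposition:
    """Per-residue interface energy table plus cholesterol cross terms.

    Invariants after :func:`summarize_table`:
    ``protomer_subtotal = Σ rows`` (full precision; an ingested published
    subtotal is kept as-is), ``chol_subtotal = chol_a_vs_b + chol_b_vs_a``,
    ``grand_total = protomer_subtotal + chol_subtotal`` and
    ``chol_fraction_percent = 100·chol_subtotal.total()/grand_total.total()``.
    """

    protomer_rows: list[EnergyTableRow] = field(default_factory=list)
    chol_a_vs_b: EnergyTerm | None = None
    chol_b_vs_a: EnergyTerm | None = None
    palm_a_vs_b: EnergyTerm | None = None  # reported, never added to totals
    palm_b_vs_a: EnergyTerm | None = None
    protomer_subtotal: EnergyTerm | None = None
    chol_subtotal: EnergyTerm | None = None
    grand_total: EnergyTerm | None = None
    chol_fraction_percent: float | None = None


@dataclass(frozen=True)
class EnergyOptions:
    """Options for the nonbonded energy evaluation.

    ``dielectric_mode`` "distance_dependent" uses ε(r) = dielectric_constant·r
    (the setup used for the force-field minimization this decomposition
    mirrors); "constant" uses ε = dielectric_constant.
    """

    residue_radius: float = 7.0
    dielectric_mode: str = "distance_dependent"
    dielectric_constant: float = 1.0
    coulomb_constant: float = COULOMB_K
    combining_rule: str = "geometric"

    def __post_init__(self) -> None:
        if self.residue_radius <= 0:
            raise ValueError("residue_radius must be > 0")
        if self.dielectric_mode not in ("constant", "distance_dependent"):
            raise ValueError(f"unknown dielectric_mode {self.dielectric_mode!r}")
        if self.combining_rule != "geometric":
            raise ValueError("only the geometric combining rule is supported")


def _block_energy(
    xyz1: np.ndarray, q1: np.ndarray, a1: np.ndarray, c1: np.ndarray,
    xyz2: np.ndarray, q2: np.ndarray, a2: np.ndarray, c2: np.ndarray,
    opts: EnergyOptions,
) -> EnergyTerm:
    """Vectorized all-pairs energy between two atom blocks."""
    r = cdist(xyz1, xyz2)
    if np.any(r == 0.0):
        raise ZeroDivisionError("coincident atoms: r_ij = 0 is singular")
    qq = np.outer(q1, q2)
    if opts.dielectric_mode == "distance_dependent":
        eps = opts.dielectric_constant * r
    else:
        eps = opts.dielectric_constant
    coul = float(np.sum(opts.coulomb_constant * qq / (eps * r)))
    aij = np.sqrt(np.outer(a1, a2))
    cij = np.sqrt(np.outer(c1, c2))
    r6 = r ** 6
    vdw = float(np.sum(aij / (r6 * r6) - cij / r6))
    return EnergyTerm(coul, vdw)


def pair_energy(atom_i: AtomRecord, atom_j: AtomRecord, opts: EnergyOptions | None = None) -> EnergyTerm:
    """Nonbonded energy of a single atom pair (kcal/mol)."""
    opts = opts or EnergyOptions()
    return _block_energy(
        atom_i.coords[None, :], np.array([atom_i.charge_q]),
        np.array([atom_i.lj_A]), np.array([atom_i.lj_C]),
        atom_j.coords[None, :], np.array([atom_j.charge_q]),
        np.array([atom_j.lj_A]), np.array([atom_j.lj_C]),
        opts,
    )


def residues_within_radius(
    anchor: Residue, pool: Sequence[Residue], radius: float
) -> list[Residue]:
    """Residues of ``pool`` whose minimum any-atom distance to ``anchor`` is
    ≤ ``radius`` (boundary inclusive)."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    pool = list(pool)
    if not pool:
        return []
    anchor_xyz = anchor.coord_array()
    pool_xyz = np.concatenate([r.coord_array() for r in pool])
    owner = np.concatenate(
        [np.full(len(r.atoms), i) for i, r in enumerate(pool)]
    )
    tree = cKDTree(pool_xyz)
    hit = set()
    for idxs in tree.query_ball_point(anchor_xyz, r=radius):
        hit.update(owner[idxs])
    return [pool[i] for i in sorted(hit)]


def residue_vs_protomer_energy(
    res: Residue,
    other: Protomer | Sequence[Residue],
    opts: EnergyOptions | None = None,
) -> EnergyTerm:
    """Energy of one residue against all residues of the opposite group that
    fall within the residue-selection radius."""
    opts = opts or EnergyOptions()
    pool = other.protein_residues if isinstance(other, Protomer) else list(other)
    selected = residues_within_radius(res, pool, opts.residue_radius)
    if not selected:
        return EnergyTerm.zero()
    xyz1, q1, a1, c1 = res.param_arrays()
    arrays = [r.param_arrays() for r in selected]
    xyz2 = np.concatenate([a[0] for a in arrays])
    q2 = np.concatenate([a[1] for a in arrays])
    a2 = np.concatenate([a[2] for a in arrays])
    c2 = np.concatenate([a[3] for a in arrays])
    return _block_energy(xyz1, q1, a1, c1, xyz2, q2, a2, c2, opts)


def decompose_interface(
    complex: DimerComplex,
    interface_positions: Sequence[str],
    opts: EnergyOptions | None = None,
) -> EnergyDecomposition:
    """Per-residue interface decomposition of a dimer complex.

    One row per listed BW position, evaluating that residue of protomer A
    against protomer B (rows for protomer B are not added — by dimer symmetry
    the one-directional sum already is the full protomer–protomer interface
    energy and adding the mirror rows would double count).  Cholesterol cross
    terms are cholesterol A vs protomer B and cholesterol B vs protomer A;
    the two cholesterols never interact with each other, nor do the two
    palmitoyls (they are sterically blocked by the apposed TMH4 helices).
    """
    opts = opts or EnergyOptions()
    rows: list[EnergyTableRow] = []
    for pos in interface_positions:
        try:
            res = complex.protomer_a.residue_at_bw(pos)
        except KeyError:
            raise KeyError(
                f"interface position {pos} not found on protomer "
                f"{complex.protomer_a.chain_id}"
            ) from None
        term = residue_vs_protomer_energy(res, complex.protomer_b, opts)
        rows.append(EnergyTableRow(residue_label=res.label, term=term))

    decomp = EnergyDecomposition(protomer_rows=rows)
    chol_a = complex.ligand("CHOL_A")
    chol_b = complex.ligand("CHOL_B")
    palm_a = complex.ligand("PALM_A")
    palm_b = complex.ligand("PALM_B")
    decomp.chol_a_vs_b = (
        residue_vs_protomer_energy(chol_a, complex.protomer_b, opts)
        if chol_a is not None else EnergyTerm.zero()
    )
    decomp.chol_b_vs_a = (
        residue_vs_protomer_energy(chol_b, complex.protomer_a, opts)
        if chol_b is not None else EnergyTerm.zero()
    )
    if palm_a is not None:
        decomp.palm_a_vs_b = residue_vs_protomer_energy(palm_a, complex.protomer_b, opts)
    if palm_b is not None:
        decomp.palm_b_vs_a = residue_vs_protomer_energy(palm_b, complex.protomer_a, opts)
    return summarize_table(decomp)


def summarize_table(decomp: EnergyDecomposition) -> EnergyDecomposition:
    """Fill subtotals, the grand total and the cholesterol contribution
    percentage.

    Subtotals are accumulated in full precision from the rows (an already
    ingested protomer subtotal — e.g. from a transcribed published table — is
    kept rather than recomputed from its rounded rows).  A grand total of
    exactly zero leaves the percentage as NaN with a warning.
    """
    if decomp.protomer_subtotal is None:
        sub = EnergyTerm.zero()
        for row in decomp.protomer_rows:
            sub = sub + row.term
        decomp.protomer_subtotal = sub
    chol_a = decomp.chol_a_vs_b or EnergyTerm.zero()
    chol_b = decomp.chol_b_vs_a or EnergyTerm.zero()
    decomp.chol_subtotal = chol_a + chol_b
    decomp.grand_total = decomp.protomer_subtotal + decomp.chol_subtotal
    gt = decomp.grand_total.total()
    if gt == 0.0:
        warnings.warn("grand total is zero; cholesterol fraction undefined")
        decomp.chol_fraction_percent = math.nan
    else:
        decomp.chol_fraction_percent = 100.0 * decomp.chol_subtotal.total() / gt
    return decomp
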
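"""Conformational Memories (CM) sampling of single transmembrane helices.

CM is a two-phase Monte-Carlo/simulated-annealing protocol.  The exploratory
phase random-walks the backbone torsion (φ/ψ) and N–Cα–C bond-angle space of
one helix down a cooling ladder (default 3000 K → 310 K in 18 geometric
steps), accepting moves by the Metropolis criterion and recording the angle
state of every accepted conformation into per-variable "memories" binned by
temperature.  The biased annealing phase (default 749.4 K → 310 K in 7
steps) then proposes only values inside the conformational space populated
at 310 K, and emits an ensemble of structures (default 105) at the final
temperature.

Each Monte-Carlo step perturbs two torsion angles and one bond angle chosen
at random.  Torsions vary within ±10° of their starting values (±50° inside
a declared flexible region such as a Pro-kink neighbourhood); bond angles
vary within ±8°.  The per-variable step count of the published protocol
(50,000 per temperature) is scaled by a single desk-scale multiplier.

The objective function is pluggable; the default is the same Coulomb +
Lennard-Jones pair energy used for the interface decomposition, applied
within the helix with 1-2/1-3 pairs excluded and 1-4 pairs scaled by 0.5.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from .structures import ONE_TO_THREE

__all__ = [
    "KB_KCAL",
    "HelixConformation",
    "VariableSet",
    "CmSchedule",
    "AngleMemory",
    "EnergyModel",
    "FlatEnergy",
    "HarmonicVariableEnergy",
    "IntraNonbondedModel",
    "ConformerEnsemble",
    "build_helix",
    "metropolis_accept",
    "exploratory_phase",
    "biased_annealing",
    "select_fitting_conformer",
]

#: Boltzmann constant, kcal/(mol·K).
KB_KCAL = 0.0019872

# Standard backbone geometry (Å, degrees)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_A_CA_C_O = 120.8
_DEFAULT_NCAC = 111.0

_BACKBONE_ATOMS = ("N", "CA", "C", "O")


def _wrap_angle(x: float) -> float:
    """Wrap to (−180, 180]."""
    x = (x + 180.0) % 360.0 - 180.0
    return 180.0 if x == -180.0 else x


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement of atom D from the A-B-C frame."""
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(chi),
        bond * math.sin(theta) * math.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass
class HelixConformation:
    """One helix: backbone internal coordinates plus derived Cartesians.

    ``phi[0]`` and ``psi[-1]``/``omega[-1]`` are undefined at the chain ends
    and held at their canonical values but never varied.  ``coords`` has
    shape (n_residues, 4, 3) for atoms N, CA, C, O and is regenerated
    deterministically from the internal coordinates by
    :meth:`rebuild_coords`; synthetic constructions (e.g. a rigid-body kink)
    may override it, in which case ``coords_from_internal`` is False.
    """

    sequence: str
    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray
    bond_angles: np.ndarray  # N-CA-C per residue
    coords: np.ndarray | None = None
    coords_from_internal: bool = True

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for name in ("phi", "psi", "omega", "bond_angles"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per residue")
            setattr(self, name, arr)
        bad = [c for c in self.sequence.upper() if c not in ONE_TO_THREE]
        if bad:
            raise ValueError(f"unknown residue letter(s): {sorted(set(bad))}")
        if self.coords is None:
            self.rebuild_coords()

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def rebuild_coords(self) -> np.ndarray:
        """Regenerate backbone Cartesians from internal coordinates (NeRF)."""
        n = self.n_residues
        xyz = np.zeros((n, 4, 3))
        # first residue frame: N at origin, CA on +x, C in the xy-plane
        xyz[0, 0] = (0.0, 0.0, 0.0)
        xyz[0, 1] = (_B_N_CA, 0.0, 0.0)
        th = math.radians(self.bond_angles[0])
        xyz[0, 2] = xyz[0, 1] + _B_CA_C * np.array([-math.cos(th), math.sin(th), 0.0])
        for i in range(n - 1):
            n_i, ca_i, c_i = xyz[i, 0], xyz[i, 1], xyz[i, 2]
            n_next = _place_atom(n_i, ca_i, c_i, _B_C_N, _A_CA_C_N, self.psi[i])
            ca_next = _place_atom(ca_i, c_i, n_next, _B_N_CA, _A_C_N_CA, self.omega[i])
            c_next = _place_atom(
                c_i, n_next, ca_next, _B_CA_C, self.bond_angles[i + 1], self.phi[i + 1]
            )
            xyz[i, 3] = _place_atom(n_i, ca_i, c_i, _B_C_O, _A_CA_C_O, self.psi[i] + 180.0)
            xyz[i + 1, 0], xyz[i + 1, 1], xyz[i + 1, 2] = n_next, ca_next, c_next
        # last carbonyl O: no next N, place trans to phi direction
        i = n - 1
        xyz[i, 3] = _place_atom(
            xyz[i, 0], xyz[i, 1], xyz[i, 2], _B_C_O, _A_CA_C_O, self.psi[i] + 180.0
        )
        self.coords = xyz
        self.coords_from_internal = True
        return xyz

    @property
    def ca_coords(self) -> np.ndarray:
        if self.coords is None:
            self.rebuild_coords()
        return self.coords[:, 1, :]

    def backbone_coords(self) -> np.ndarray:
        """Flat (4n, 3) array in N, CA, C, O order per residue."""
        if self.coords is None:
            self.rebuild_coords()
        return self.coords.reshape(-1, 3)

    # -- variable access used by the sampler -------------------------------
    def get_variable(self, var: tuple[str, int]) -> float:
        kind, i = var
        if kind == "phi":
            return float(self.phi[i])
        if kind == "psi":
            return float(self.psi[i])
        if kind == "theta":
            return float(self.bond_angles[i])
        raise KeyError(var)

    def set_variable(self, var: tuple[str, int], value: float) -> None:
        kind, i = var
        if kind == "phi":
            self.phi[i] = _wrap_angle(value)
        elif kind == "psi":
            self.psi[i] = _wrap_angle(value)
        elif kind == "theta":
            self.bond_angles[i] = value
        else:
            raise KeyError(var)
        self.coords_from_internal = False  # coords stale until rebuilt

    def copy(self) -> "HelixConformation":
        return HelixConformation(
            sequence=self.sequence,
            phi=self.phi.copy(),
            psi=self.psi.copy(),
            omega=self.omega.copy(),
            bond_angles=self.bond_angles.copy(),
            coords=None if self.coords is None else self.coords.copy(),
            coords_from_internal=self.coords_from_internal,
        )


def build_helix(sequence: str, phi: float = -63.0, psi: float = -41.6) -> HelixConformation:
    """Build an ideal α-helix at the standard transmembrane backbone
    dihedrals φ = −63°, ψ = −41.6° (ω = 180°, standard bond geometry).

    Deterministic: the same call always yields identical coordinates.
    """
    n = len(sequence)
    if n < 5:
        raise ValueError("sequence must have at least 5 residues")
    return HelixConformation(
        sequence=sequence,
        phi=np.full(n, phi),
        psi=np.full(n, psi),
        omega=np.full(n, 180.0),
        bond_angles=np.full(n, _DEFAULT_NCAC),
    )


@dataclass
class VariableSet:
    """The variable angles of one CM run and their half-windows (degrees).

    ``torsion_windows`` maps ("phi"|"psi", residue_index) → half-width;
    ``bond_angle_windows`` maps residue_index → half-width.  Windows are
    centred on the helix's starting values.
    """

    torsion_windows: dict[tuple[str, int], float] = field(default_factory=dict)
    bond_angle_windows: dict[int, float] = field(default_factory=dict)
    flexible_region: tuple[int, int] | None = None

    @classmethod
    def for_helix(
        cls,
        helix: HelixConformation,
        flexible_region: tuple[int, int] | None = None,
        torsion_halfwidth: float = 10.0,
        flexible_halfwidth: float = 50.0,
        bond_halfwidth: float = 8.0,
        include_bond_angles: bool = True,
    ) -> "VariableSet":
        """Default variable set: all interior φ/ψ at ±10° (±50° inside the
        flexible residue span, 0-based inclusive) and all N–Cα–C bond angles
        at ±8°."""
        n = helix.n_residues
        tw: dict[tuple[str, int], float] = {}

        def width(i: int) -> float:
            if flexible_region and flexible_region[0] <= i <= flexible_region[1]:
                return flexible_halfwidth
            return torsion_halfwidth

        for i in range(1, n):
            tw[("phi", i)] = width(i)
        for i in range(0, n - 1):
            tw[("psi", i)] = width(i)
        bw = {i: bond_halfwidth for i in range(n)} if include_bond_angles else {}
        return cls(torsion_windows=tw, bond_angle_windows=bw, flexible_region=flexible_region)

    @property
    def torsion_vars(self) -> list[tuple[str, int]]:
        return list(self.torsion_windows)

    @property
    def bond_vars(self) -> list[tuple[str, int]]:
        return [("theta", i) for i in self.bond_angle_windows]

    def all_vars(self) -> list[tuple[str, int]]:
        return self.torsion_vars + self.bond_vars

    def half_width(self, var: tuple[str, int]) -> float:
        kind, i = var
        if kind == "theta":
            return self.bond_angle_windows[i]
        return self.torsion_windows[(kind, i)]


@dataclass
class CmSchedule:
    """Temperatures and step counts of the two CM phases.

    Defaults follow the published protocol: exploratory 3000 K → 310 K in 18
    geometric steps with 50,000 trial moves per temperature; biased annealing
    749.4 K → 310 K in 7 steps; 105 structures output at 310 K.  ``scale``
    is the desk-scale multiplier applied to ``steps_per_variable``.
    """

    t_initial: float = 3000.0
    steps_per_variable: int = 50_000
    cooling_steps_exploratory: int = 18
    t_final: float = 310.0
    t_biased_start: float = 749.4
    cooling_steps_biased: int = 7
    n_output: int = 105
    cooling_law: str = "geometric"
    scale: float = 1.0
    snapshot_stride: int = 5

    def __post_init__(self) -> None:
        if not (self.t_initial > self.t_biased_start > self.t_final > 0):
            raise ValueError("require t_initial > t_biased_start > t_final > 0")
        if self.cooling_law != "geometric":
            raise ValueError("only geometric cooling is implemented")

    def _ladder(self, t0: float, tf: float, k: int) -> np.ndarray:
        # endpoints inclusive: stage j of k has T = t0 * (tf/t0)^(j/(k-1))
        if k == 1:
            return np.array([tf])
        j = np.arange(k)
        return t0 * (tf / t0) ** (j / (k - 1))

    def exploratory_temperatures(self) -> np.ndarray:
        return self._ladder(self.t_initial, self.t_final, self.cooling_steps_exploratory)

    def biased_temperatures(self) -> np.ndarray:
        return self._ladder(self.t_biased_start, self.t_final, self.cooling_steps_biased)

    @property
    def steps_per_stage(self) -> int:
        return max(1, round(self.steps_per_variable * self.scale))


class AngleMemory:
    """Per-variable histograms of accepted angle values, by temperature stage.

    Bin widths default to 5° for torsions and 2° for bond angles; bins tile
    each variable's window.  ``populated_final`` (the 310 K map) is what the
    biased phase samples from.
    """

    def __init__(
        self,
        variables: VariableSet,
        centers: dict[tuple[str, int], float],
        n_stages: int,
        torsion_bin_width: float = 5.0,
        bond_bin_width: float = 2.0,
    ) -> None:
        self.variables = variables
        self.centers = dict(centers)
        self.n_stages = n_stages
        self.torsion_bin_width = torsion_bin_width
        self.bond_bin_width = bond_bin_width
        self.fallback_used: set[tuple[str, int]] = set()
        self._edges: dict[tuple[str, int], np.ndarray] = {}
        self._counts: dict[tuple[str, int], np.ndarray] = {}
        for var in variables.all_vars():
            half = variables.half_width(var)
            width = bond_bin_width if var[0] == "theta" else torsion_bin_width
            n_bins = max(1, int(math.ceil(2 * half / width)))
            lo = centers[var] - half
            self._edges[var] = lo + np.arange(n_bins + 1) * (2 * half / n_bins)
            self._counts[var] = np.zeros((n_stages, n_bins), dtype=np.int64)

    def bin_index(self, var: tuple[str, int], value: float) -> int:
        edges = self._edges[var]
        idx = int(np.searchsorted(edges, value, side="right") - 1)
        return min(max(idx, 0), len(edges) - 2)

    def record(self, var: tuple[str, int], value: float, stage: int) -> None:
        self._counts[var][stage, self.bin_index(var, value)] += 1

    def counts(self, var: tuple[str, int], stage: int) -> np.ndarray:
        return self._counts[var][stage]

    def edges(self, var: tuple[str, int]) -> np.ndarray:
        return self._edges[var]

    def populated_bins(self, var: tuple[str, int], stage: int = -1) -> np.ndarray:
        """Indices of occupied bins at the given stage (default: final/310 K)."""
        return np.nonzero(self._counts[var][stage] > 0)[0]

    def coverage(self, var: tuple[str, int], stage: int = -1) -> float:
        """Fraction of the variable's window bins occupied at the stage."""
        c = self._counts[var][stage]
        return float(np.count_nonzero(c)) / len(c)

    def contains(self, var: tuple[str, int], value: float, stage: int = -1) -> bool:
        return self._counts[var][stage, self.bin_index(var, value)] > 0

    def mean_accepted(self, var: tuple[str, int], stage: int = -1) -> float:
        """Count-weighted mean of bin centres at the stage."""
        c = self._counts[var][stage].astype(float)
        if c.sum() == 0:
            return math.nan
        edges = self._edges[var]
        centers = 0.5 * (edges[:-1] + edges[1:])
        return float(np.average(centers, weights=c))

    def sample_value(self, var: tuple[str, int], rng: np.random.Generator,
                     stage: int = -1) -> float:
        """Uniform draw: pick an occupied bin uniformly, then a value
        uniformly inside it.  Falls back to the full window (flagged via
        ``fallback_used``) when the variable has no occupied bins."""
        occ = self.populated_bins(var, stage)
        edges = self._edges[var]
        if len(occ) == 0:
            self.fallback_used.add(var)
            return float(rng.uniform(edges[0], edges[-1]))
        b = occ[rng.integers(len(occ))]
        return float(rng.uniform(edges[b], edges[b + 1]))

    def empty_variables(self, stage: int = -1) -> list[tuple[str, int]]:
        return [v for v in self.variables.all_vars() if len(self.populated_bins(v, stage)) == 0]


# --------------------------------------------------------------------------
# Energy models
# --------------------------------------------------------------------------

class EnergyModel:
    """Objective-function interface: ``energy(helix) -> kcal/mol``.

    ``needs_coords`` tells the sampler whether Cartesians must be rebuilt
    before each evaluation (angle-space toy models skip that cost).
    """

    needs_coords: bool = True

    def energy(self, helix: HelixConformation) -> float:  # pragma: no cover
        raise NotImplementedError


class FlatEnergy(EnergyModel):
    """E ≡ 0: every move is accepted; samples the prior over the windows."""

    needs_coords = False

    def energy(self, helix: HelixConformation) -> float:
        return 0.0


class HarmonicVariableEnergy(EnergyModel):
    """Harmonic well on a single variable: E = ½·k·(x − x₀)², in kcal/mol
    with x in degrees.  A 1-D toy whose Boltzmann marginal is Gaussian."""

    needs_coords = False

    def __init__(self, var: tuple[str, int], center: float, k: float) -> None:
        self.var = var
        self.center = center
        self.k = k

    def energy(self, helix: HelixConformation) -> float:
        x = helix.get_variable(self.var)
        return 0.5 * self.k * (x - self.center) ** 2


class IntraNonbondedModel(EnergyModel):
    """Intra-helix nonbonded energy: the same Coulomb + 12-6 pair function as
    the interface decomposition, restricted to atom pairs more than three
    bonds apart (1-2/1-3 excluded, 1-4 scaled by 0.5).

    Default parameters are generic backbone values (zero charges; per-element
    Lennard-Jones A/C from common σ/ε); the model is a smooth steric term,
    not a calibrated force field.
    """

    needs_coords = True

    # per-element (A_ii kcal·Å¹²/mol, C_ii kcal·Å⁶/mol), from 4εσ¹²/4εσ⁶
    _LJ = {"N": (9.4e5, 800.0), "C": (8.9e5, 485.0), "O": (3.8e5, 565.0)}

    def __init__(self, n_residues: int, charges: np.ndarray | None = None,
                 one_four_scale: float = 0.5) -> None:
        n_atoms = 4 * n_residues
        elements = np.tile(["N", "C", "C", "O"], n_residues)
        self._a = np.array([self._LJ[e][0] for e in elements])
        self._c = np.array([self._LJ[e][1] for e in elements])
        self._q = np.zeros(n_atoms) if charges is None else np.asarray(charges, float)
        self._scale = self._pair_scale_matrix(n_residues, one_four_scale)

    @staticmethod
    def _pair_scale_matrix(n_residues: int, one_four_scale: float) -> np.ndarray:
        """Bond-distance-based scale factors: 0 for 1-2/1-3 pairs (≤ 2 bonds
        apart), ``one_four_scale`` for 1-4 pairs (3 bonds), 1 beyond."""
        n_atoms = 4 * n_residues
        adj: list[list[int]] = [[] for _ in range(n_atoms)]

        def bond(i: int, j: int) -> None:
            adj[i].append(j)
            adj[j].append(i)

        for r in range(n_residues):
            b = 4 * r
            bond(b, b + 1)      # N-CA
            bond(b + 1, b + 2)  # CA-C
            bond(b + 2, b + 3)  # C-O
            if r + 1 < n_residues:
                bond(b + 2, 4 * (r + 1))  # C-N(next)
        scale = np.ones((n_atoms, n_atoms))
        for i in range(n_atoms):
            # BFS to depth 3
            dist = {i: 0}
            frontier = [i]
            for d in (1, 2, 3):
                nxt = []
                for u in frontier:
                    for v in adj[u]:
                        if v not in dist:
                            dist[v] = d
                            nxt.append(v)
                frontier = nxt
            for j, d in dist.items():
                if d <= 2:
                    scale[i, j] = 0.0
                elif d == 3:
                    scale[i, j] = one_four_scale
        np.fill_diagonal(scale, 0.0)
        return scale

    def energy(self, helix: HelixConformation) -> float:
        from .energetics import COULOMB_K

        xyz = helix.backbone_coords()
        r = squareform(pdist(xyz))
        np.fill_diagonal(r, np.inf)
        aij = np.sqrt(np.outer(self._a, self._a))
        cij = np.sqrt(np.outer(self._c, self._c))
        r6 = r ** 6
        vdw = aij / (r6 * r6) - cij / r6
        coul = COULOMB_K * np.outer(self._q, self._q) / (r * r)  # ε(r) = r
        return float(0.5 * np.sum(self._scale * (vdw + coul)))


# --------------------------------------------------------------------------
# Sampling
# --------------------------------------------------------------------------

def metropolis_accept(delta_e: float, temperature: float, rng: np.random.Generator) -> bool:
    """Metropolis criterion: accept with probability min(1, e^(−ΔE/kBT))."""
    if not math.isfinite(delta_e):
        raise ValueError("non-finite energy change")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if delta_e <= 0:
        return True
    return rng.random() < math.exp(-delta_e / (KB_KCAL * temperature))


def _choose_move(vars_: VariableSet, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Two torsions + one bond angle per step (degenerate sets take what is
    available)."""
    tv, bv = vars_.torsion_vars, vars_.bond_vars
    chosen: list[tuple[str, int]] = []
    if tv:
        k = min(2, len(tv))
        idx = rng.choice(len(tv), size=k, replace=False)
        chosen.extend(tv[i] for i in idx)
    if bv:
        chosen.append(bv[rng.integers(len(bv))])
    return chosen


def _evaluate(model: EnergyModel, helix: HelixConformation) -> float:
    if model.needs_coords:
        helix.rebuild_coords()
    return model.energy(helix)


def exploratory_phase(
    helix: HelixConformation,
    variables: VariableSet,
    schedule: CmSchedule,
    model: EnergyModel,
    seed: int,
) -> AngleMemory:
    """Phase 1: map the accessible angle space down the cooling ladder.

    Returns the completed :class:`AngleMemory`; the occupied bins at the last
    (310 K) stage are the populated space the biased phase will use.  The
    per-stage acceptance ratios are attached as ``memory.acceptance_by_stage``.
    """
    if not variables.all_vars():
        raise ValueError("variable set is empty")
    rng = np.random.default_rng(seed)
    state = helix.copy()
    temps = schedule.exploratory_temperatures()
    centers = {v: state.get_variable(v) for v in variables.all_vars()}
    memory = AngleMemory(variables, centers, n_stages=len(temps))
    current_e = _evaluate(model, state)
    acceptance: list[float] = []
    for stage, temp in enumerate(temps):
        n_acc = 0
        for _ in range(schedule.steps_per_stage):
            moved = _choose_move(variables, rng)
            old = [(v, state.get_variable(v)) for v in moved]
            for v in moved:
                half = variables.half_width(v)
                state.set_variable(v, rng.uniform(centers[v] - half, centers[v] + half))
            new_e = _evaluate(model, state)
            if metropolis_accept(new_e - current_e, temp, rng):
                current_e = new_e
                n_acc += 1
                # memories record the whole accepted conformation
                for v in variables.all_vars():
                    memory.record(v, state.get_variable(v), stage)
            else:
                for v, val in old:
                    state.set_variable(v, val)
        acceptance.append(n_acc / schedule.steps_per_stage)
    memory.acceptance_by_stage = acceptance  # type: ignore[attr-defined]
    return memory


@dataclass
class ConformerEnsemble:
    """Output of the biased annealing phase."""

    conformers: list[HelixConformation]
    n_proposals: int
    out_of_memory_proposals: int
    acceptance_by_stage: list[float]

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    def __getitem__(self, i):
        return self.conformers[i]


def biased_annealing(
    helix: HelixConformation,
    memory: AngleMemory,
    schedule: CmSchedule,
    model: EnergyModel,
    seed: int,
) -> ConformerEnsemble:
    """Phase 2: anneal with proposals restricted to the populated 310 K space
    and emit ``schedule.n_output`` structures at the final temperature."""
    empty = memory.empty_variables()
    if empty:
        raise ValueError(
            f"variables with empty populated space at the final temperature: {empty}"
        )
    rng = np.random.default_rng(seed)
    variables = memory.variables
    state = helix.copy()
    # start inside populated space
    for v in variables.all_vars():
        state.set_variable(v, memory.sample_value(v, rng))
    current_e = _evaluate(model, state)
    n_prop = 0
    n_out_of_memory = 0
    acceptance: list[float] = []
    conformers: list[HelixConformation] = []

    def do_steps(n_steps: int, temp: float) -> float:
        nonlocal current_e, n_prop, n_out_of_memory
        n_acc = 0
        for _ in range(n_steps):
            moved = _choose_move(variables, rng)
            old = [(v, state.get_variable(v)) for v in moved]
            for v in moved:
                val = memory.sample_value(v, rng)
                n_prop += 1
                if not memory.contains(v, val):
                    n_out_of_memory += 1
                state.set_variable(v, val)
            new_e = _evaluate(model, state)
            if metropolis_accept(new_e - current_e, temp, rng):
                current_e = new_e
                n_acc += 1
            else:
                for v, val in old:
                    state.set_variable(v, val)
        return n_acc / max(1, n_steps)

    for temp in schedule.biased_temperatures():
        acceptance.append(do_steps(schedule.steps_per_stage, temp))
    for _ in range(schedule.n_output):
        do_steps(schedule.snapshot_stride, schedule.t_final)
        snap = state.copy()
        snap.rebuild_coords()
        conformers.append(snap)
    return ConformerEnsemble(
        conformers=conformers,
        n_proposals=n_prop,
        out_of_memory_proposals=n_out_of_memory,
        acceptance_by_stage=acceptance,
    )


def select_fitting_conformer(
    candidates: Sequence[HelixConformation],
    bundle_coords: np.ndarray | None,
    clash_cutoff: float,
    template_ca: np.ndarray | None = None,
) -> HelixConformation | None:
    """First candidate (in input order) that, after superposition onto the
    template helix position, has no interatomic distance below
    ``clash_cutoff`` against the rest of the bundle.

    ``bundle_coords`` are the atoms of the *other* helices (None/empty means
    nothing to clash with → first candidate wins).  ``template_ca`` gives the
    Cα positions of the template helix to superpose onto; without it the
    candidates are tested in place.  Returns None when every candidate
    clashes.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidates")
    if bundle_coords is None or len(bundle_coords) == 0:
        return candidates[0]
    bundle_coords = np.asarray(bundle_coords, float)
    for cand in candidates:
        atoms = cand.backbone_coords()
        if template_ca is not None:
            atoms = _superpose(cand.ca_coords, np.asarray(template_ca, float), atoms)
        d_min = np.min(
            np.linalg.norm(atoms[:, None, :] - bundle_coords[None, :, :], axis=-1)
        )
        if d_min >= clash_cutoff:
            return cand
    return None


def _superpose(mobile_ca: np.ndarray, target_ca: np.ndarray, atoms: np.ndarray) -> np.ndarray:
    """Kabsch superposition of ``mobile_ca`` onto ``target_ca``; applies the
    transform to ``atoms``."""
    k = min(len(mobile_ca), len(target_ca))
    m, t = mobile_ca[:k], target_ca[:k]
    mc, tc = m.mean(axis=0), t.mean(axis=0)
    rot, _ = Rotation.align_vectors(t - tc, m - mc)
    return rot.apply(atoms - mc) + tc
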
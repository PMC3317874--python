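"""Molecular data model and PDB I/O for dimer interface analysis.

The central objects are :class:`AtomRecord`, :class:`Residue`,
:class:`Protomer` and :class:`DimerComplex`.  A protomer is one receptor
subunit of a homodimer; residues may carry Ballesteros–Weinstein (BW)
positions ("<helix>.<index>", e.g. "4.44") supplied by the user — no BW
inference is attempted.  Lipid ligands (cholesterol, palmitoyl) are residues
flagged ``is_ligand`` with a tag recording which protomer they belong to
("CHOL_A", "PALM_B", ...).

Coordinates are Cartesian angstroms in a right-handed frame, exactly as read
from the PDB file.  Nonbonded parameters (partial charge q, Lennard-Jones
A and C self-coefficients) are attached from a user table; the PDB format
itself carries none.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomRecord",
    "Residue",
    "Protomer",
    "DimerComplex",
    "PdbParseError",
    "ConfigError",
    "MissingParameterError",
    "read_pdb",
    "write_pdb",
    "attach_parameters",
    "load_parameter_table",
    "DEFAULT_LIGAND_TAGS",
]

_BW_PATTERN = re.compile(r"^\d+\.\d+$")

#: Default mapping of PDB residue names to ligand tag stems.  The protomer
#: suffix ("_A"/"_B") is appended from the chain the ligand sits in.
DEFAULT_LIGAND_TAGS: dict[str, str] = {"CLR": "CHOL", "PLM": "PALM"}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


class PdbParseError(ValueError):
    """Raised for malformed PDB coordinate records; names the line number."""


class ConfigError(ValueError):
    """Raised when the BW map / ligand-tag config references unknown entities."""


class MissingParameterError(KeyError):
    """Raised when atoms lack nonbonded parameters and no default is declared."""


@dataclass
class AtomRecord:
    """One atom: name, element, coordinates (Å) and nonbonded parameters.

    ``charge_q`` is the partial charge in elementary charges; ``lj_A`` and
    ``lj_C`` are the repulsive (kcal·Å¹²/mol) and dispersive (kcal·Å⁶/mol)
    Lennard-Jones self-coefficients.  Parameters default to NaN until
    :func:`attach_parameters` fills them.
    """

    atom_name: str
    element: str
    coords: np.ndarray
    charge_q: float = np.nan
    lj_A: float = np.nan
    lj_C: float = np.nan

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.atom_name}: coords must be a finite 3-vector")
        for name in ("lj_A", "lj_C"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"atom {self.atom_name}: {name} must be >= 0")

    @property
    def parameterized(self) -> bool:
        return bool(
            np.isfinite(self.charge_q)
            and np.isfinite(self.lj_A)
            and np.isfinite(self.lj_C)
        )


@dataclass
class Residue:
    """A residue (or lipid ligand) with its ordered atoms.

    ``bw_position`` is the Ballesteros–Weinstein label when the user map
    provides one.  ``ligand_tag`` identifies lipids: "CHOL_A" is the
    cholesterol associated with protomer A, etc.
    """

    seq_number: int
    aa_code: str
    atoms: list[AtomRecord] = field(default_factory=list)
    bw_position: str | None = None
    is_ligand: bool = False
    ligand_tag: str | None = None

    def __post_init__(self) -> None:
        if self.bw_position is not None and not _BW_PATTERN.match(self.bw_position):
            raise ValueError(
                f"residue {self.seq_number}: BW position {self.bw_position!r} "
                "does not match '<TM#>.<index>'"
            )

    @property
    def one_letter(self) -> str:
        code = self.aa_code.upper()
        if len(code) == 1:
            return code
        return _THREE_TO_ONE.get(code, "X")

    @property
    def label(self) -> str:
        """Table label, e.g. 'I4.44' when a BW position is known."""
        if self.bw_position:
            return f"{self.one_letter}{self.bw_position}"
        return f"{self.one_letter}{self.seq_number}"

    def coord_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def param_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(coords, q, A, C) arrays; raises if any atom is unparameterized."""
        missing = [a.atom_name for a in self.atoms if not a.parameterized]
        if missing:
            raise MissingParameterError(
                f"residue {self.seq_number} ({self.aa_code}): unparameterized "
                f"atoms {missing}"
            )
        return (
            self.coord_array(),
            np.array([a.charge_q for a in self.atoms]),
            np.array([a.lj_A for a in self.atoms]),
            np.array([a.lj_C for a in self.atoms]),
        )


@dataclass
class Protomer:
    """One subunit of the dimer: an ordered chain of residues.

    ``helix_segments`` maps a transmembrane-helix number to the
    (first_seq, last_seq) residue span of that helix.
    """

    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    helix_segments: dict[int, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for r in self.residues:
            if r.seq_number in seen:
                raise ValueError(
                    f"chain {self.chain_id}: duplicate residue number {r.seq_number}"
                )
            seen.add(r.seq_number)
        bw_seen: dict[str, int] = {}
        for r in self.residues:
            if r.bw_position is not None:
                if r.bw_position in bw_seen:
                    raise ValueError(
                        f"chain {self.chain_id}: BW position {r.bw_position} assigned "
                        f"to both residues {bw_seen[r.bw_position]} and {r.seq_number}"
                    )
                bw_seen[r.bw_position] = r.seq_number
        spans = sorted(self.helix_segments.values())
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 <= a1:
                raise ValueError(f"chain {self.chain_id}: helix segments overlap")

    def residue_by_number(self, seq_number: int) -> Residue:
        for r in self.residues:
            if r.seq_number == seq_number:
                return r
        raise KeyError(f"chain {self.chain_id}: no residue {seq_number}")

    def residue_at_bw(self, bw_position: str) -> Residue:
        for r in self.residues:
            if r.bw_position == bw_position:
                return r
        raise KeyError(f"chain {self.chain_id}: no residue at BW position {bw_position}")

    @property
    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.is_ligand]


@dataclass
class DimerComplex:
    """Two protomers plus their lipid ligands.

    At most two cholesterols are allowed and each must be assigned to exactly
    one protomer through its ``ligand_tag`` suffix.
    """

    protomer_a: Protomer
    protomer_b: Protomer
    ligands: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        chols = [l for l in self.ligands if (l.ligand_tag or "").startswith("CHOL")]
        if len(chols) > 2:
            raise ValueError(f"at most 2 cholesterol ligands allowed, got {len(chols)}")
        for l in self.ligands:
            if not l.is_ligand:
                raise ValueError(f"ligand list contains non-ligand residue {l.seq_number}")
            tag = l.ligand_tag or ""
            if tag.startswith("CHOL") and not tag.endswith(("_A", "_B")):
                raise ValueError(
                    f"cholesterol {l.seq_number} must be assigned to one protomer "
                    f"via its tag (got {tag!r})"
                )

    def ligand(self, tag: str) -> Residue | None:
        for l in self.ligands:
            if l.ligand_tag == tag:
                return l
        return None

    def all_residues(self) -> list[Residue]:
        return (
            self.protomer_a.residues + self.protomer_b.residues + list(self.ligands)
        )


def _prescan_pdb(path: Path) -> None:
    """Check ATOM/HETATM records for truncated/unparseable coordinate fields.

    PDB is fixed-column; coordinates occupy columns 31-54.  This pass exists
    only to report the offending line number, which the downstream reader
    does not do.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            stripped = line.rstrip("\n")
            if len(stripped) < 54:
                raise PdbParseError(
                    f"{path}, line {lineno}: coordinate record truncated "
                    f"({len(stripped)} columns, need >= 54)"
                )
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(stripped[lo:hi])
                except ValueError:
                    raise PdbParseError(
                        f"{path}, line {lineno}: unparseable coordinate field "
                        f"{stripped[lo:hi]!r}"
                    ) from None


def read_pdb(
    path: str | Path,
    bw_map: Mapping[int, str] | None = None,
    ligand_tags: Mapping[str, str] | None = None,
    helix_segments: Mapping[str, Mapping[int, tuple[int, int]]] | None = None,
) -> DimerComplex:
    """Read a dimer complex from a PDB file.

    Parameters
    ----------
    path:
        PDB file with at least one chain.  The first two (protein-containing)
        chains become protomers A and B, in file order.
    bw_map:
        Sequence number → BW position (applied to both protomers; residue
        numbering is assumed shared across the homodimer).
    ligand_tags:
        PDB residue name → tag stem ("CLR" → "CHOL").  A full tag with an
        explicit "_A"/"_B" suffix is used verbatim; a stem gets the suffix of
        the chain the ligand occupies.
    helix_segments:
        Optional chain_id → {TMH#: (first_seq, last_seq)}.
    """
    path = Path(path)
    _prescan_pdb(path)
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1)
    if arr.array_length() == 0:
        raise PdbParseError(f"{path}: no atoms")

    bw_map = dict(bw_map or {})
    tags = dict(DEFAULT_LIGAND_TAGS)
    if ligand_tags:
        tags.update(ligand_tags)

    chain_order: list[str] = []
    for cid in arr.chain_id:
        if cid not in chain_order:
            chain_order.append(cid)

    if helix_segments:
        unknown = set(helix_segments) - set(chain_order)
        if unknown:
            raise ConfigError(f"helix_segments references unknown chains {sorted(unknown)}")

    protein_chains = [
        cid
        for cid in chain_order
        if np.any((arr.chain_id == cid) & ~np.isin(arr.res_name, list(tags)))
    ]
    if not protein_chains:
        raise PdbParseError(f"{path}: no protein chains found")

    protomers: dict[str, Protomer] = {}
    ligands: list[Residue] = []
    for cid in chain_order:
        mask = arr.chain_id == cid
        sub = arr[mask]
        residues: list[Residue] = []
        for res_id in pd.unique(sub.res_id):
            rmask = sub.res_id == res_id
            res_name = sub.res_name[rmask][0]
            atoms = [
                AtomRecord(atom_name=an, element=el, coords=xyz)
                for an, el, xyz in zip(
                    sub.atom_name[rmask], sub.element[rmask], sub.coord[rmask]
                )
            ]
            is_lig = res_name in tags
            tag = None
            if is_lig:
                stem = tags[res_name]
                tag = stem if "_" in stem else f"{stem}_{_protomer_letter(cid, protein_chains)}"
            res = Residue(
                seq_number=int(res_id),
                aa_code=str(res_name),
                atoms=atoms,
                bw_position=bw_map.get(int(res_id)) if not is_lig else None,
                is_ligand=is_lig,
                ligand_tag=tag,
            )
            if is_lig:
                ligands.append(res)
            else:
                residues.append(res)
        if residues:
            segs = dict((helix_segments or {}).get(cid, {}))
            protomers[cid] = Protomer(chain_id=cid, residues=residues, helix_segments=segs)

    if len(protomers) == 1:
        only = next(iter(protomers.values()))
        cx = DimerComplex(
            protomer_a=only,
            protomer_b=Protomer(chain_id="_", residues=[]),
            ligands=ligands,
        )
        return cx
    a_id, b_id = protein_chains[0], protein_chains[1]
    return DimerComplex(protomer_a=protomers[a_id], protomer_b=protomers[b_id], ligands=ligands)


def _protomer_letter(chain_id: str, protein_chains: Sequence[str]) -> str:
    if chain_id in protein_chains:
        return "A" if chain_id == protein_chains[0] else "B"
    # HETATM-only chain: ligands in their own chain map by order A, B
    return "A" if chain_id <= protein_chains[0] else "B"


def load_parameter_table(path: str | Path) -> dict[tuple[str, str], tuple[float, float, float]]:
    """Load a nonbonded parameter TSV.

    Columns: residue_name, atom_name, charge_e, lj_A, lj_C.  A row with
    residue_name ``*`` (and/or atom_name ``*``) acts as a wildcard default.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"residue_name", "atom_name", "charge_e", "lj_A", "lj_C"}
    if not required.issubset(df.columns):
        raise ValueError(f"parameter table must have columns {sorted(required)}")
    table: dict[tuple[str, str], tuple[float, float, float]] = {}
    for row in df.itertuples(index=False):
        table[(str(row.residue_name), str(row.atom_name))] = (
            float(row.charge_e),
            float(row.lj_A),
            float(row.lj_C),
        )
    return table


def attach_parameters(
    complex: DimerComplex,
    params: Mapping[tuple[str, str], tuple[float, float, float]],
    default: tuple[float, float, float] | None = None,
) -> DimerComplex:
    """Attach (q, A, C) to every atom, in place; returns the complex.

    Lookup order: (residue, atom), ("*", atom), (residue, "*"), ("*", "*"),
    then the ``default`` argument.  Missing parameters with no default raise
    :class:`MissingParameterError` listing every offending (residue, atom).
    """
    missing: list[tuple[str, str]] = []
    for res in complex.all_residues():
        for atom in res.atoms:
            keys = [
                (res.aa_code, atom.atom_name),
                ("*", atom.atom_name),
                (res.aa_code, "*"),
                ("*", "*"),
            ]
            val = next((params[k] for k in keys if k in params), default)
            if val is None:
                missing.append((res.aa_code, atom.atom_name))
                continue
            atom.charge_q, atom.lj_A, atom.lj_C = (float(v) for v in val)
    if missing:
        raise MissingParameterError(
            f"no parameters (and no default) for atoms: {sorted(set(missing))}"
        )
    return complex


def write_pdb(complex: DimerComplex, path: str | Path) -> None:
    """Write the complex as a PDB file (ligands as HETATM)."""
    entries: list[tuple[str, Residue]] = []
    for prot in (complex.protomer_a, complex.protomer_b):
        for res in prot.residues:
            entries.append((prot.chain_id, res))
    lig_chain = {
        None: complex.protomer_a.chain_id,
        "A": complex.protomer_a.chain_id,
        "B": complex.protomer_b.chain_id,
    }
    for lig in complex.ligands:
        suffix = (lig.ligand_tag or "").rsplit("_", 1)[-1] if lig.ligand_tag else None
        entries.append((lig_chain.get(suffix, complex.protomer_a.chain_id), lig))

    n_atoms = sum(len(res.atoms) for _, res in entries)
    if n_atoms == 0:
        raise ValueError("cannot write an empty complex")
    arr = struc.AtomArray(n_atoms)
    i = 0
    for cid, res in entries:
        for atom in res.atoms:
            arr.chain_id[i] = cid
            arr.res_id[i] = res.seq_number
            name = res.aa_code if len(res.aa_code) <= 3 else res.aa_code[:3]
            arr.res_name[i] = name if len(res.aa_code) > 1 else ONE_TO_THREE.get(res.aa_code, "UNK")
            arr.atom_name[i] = atom.atom_name
            arr.element[i] = atom.element
            arr.hetero[i] = res.is_ligand
            arr.coord[i] = atom.coords
            i += 1
    out = PDBFile()
    out.set_structure(arr)
    out.write(str(path))
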
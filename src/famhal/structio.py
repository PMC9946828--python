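"""Backbone structure I/O and inspection utilities.

Reads and writes protein backbones in PDB format, reconstructs ideal
virtual Cβ atoms, and provides the small inspection helpers (residue
count, chain mass, inter-atom distances) used to examine design models.

Parsing is delegated to gemmi; the documented alternate-location policy
(highest occupancy, ties broken alphabetically) and insertion-code
ordering are applied on top of gemmi's atom lists.  Writing uses plain
fixed-width PDB record formatting so that fixture output is
byte-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Residue",
    "BackboneStructure",
    "StructIOError",
    "EmptyStructureError",
    "MissingBackboneAtomError",
    "PDBFormatError",
    "SelectionError",
    "UnknownResidueError",
    "read_pdb",
    "write_pdb",
    "reconstruct_cb",
    "residue_count",
    "chain_mass",
    "atom_distance",
    "one_letter_sequence",
    "place_internal",
    "IDEAL_CB",
]


class StructIOError(ValueError):
    """Base class for structure-I/O errors."""


class EmptyStructureError(StructIOError):
    """Raised when a PDB file contains no ATOM records."""


class MissingBackboneAtomError(StructIOError):
    """Raised when a polymer residue lacks one of N, CA, C."""


class PDBFormatError(StructIOError):
    """Raised when a PDB file cannot be parsed."""


class SelectionError(StructIOError):
    """Raised when an atom selection is empty or ambiguous."""


class UnknownResidueError(StructIOError):
    """Raised for amino-acid letters outside the standard alphabet."""


BACKBONE_ATOMS = ("N", "CA", "C")

#: Ideal internal coordinates for a virtual Cβ: bond CA–CB in Å,
#: planar angle N–CA–CB in degrees, dihedral C–N–CA–CB in degrees.
IDEAL_CB = (1.522, 110.4, -122.5)

# Average (not monoisotopic) residue masses in Da, i.e. amino-acid mass
# minus one water; a free chain adds one water back.
RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class Residue:
    """One polymer residue: 3-letter name, PDB residue number, atom map."""

    name: str
    number: int
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in BACKBONE_ATOMS)


@dataclass
class BackboneStructure:
    """An ordered single-chain backbone plus any hetero-group atoms.

    ``hetero_atoms`` holds ``(group_name, atom_name, coordinate)`` tuples
    for HETATM records (ligands, waters) on the same chain.
    """

    residues: list[Residue]
    hetero_atoms: list[tuple[str, str, np.ndarray]] = field(default_factory=list)
    chain_id: str = "A"

    def __len__(self) -> int:
        return len(self.residues)

    def coords(self, atom: str) -> np.ndarray:
        """(L, 3) array of one backbone atom type across all residues."""
        try:
            return np.array([r.atoms[atom] for r in self.residues], dtype=float)
        except KeyError:
            missing = next(r for r in self.residues if atom not in r.atoms)
            raise MissingBackboneAtomError(
                f"residue {missing.name}{missing.number} lacks atom {atom}"
            ) from None

    def validate(self) -> None:
        prev = None
        for r in self.residues:
            if not r.has_backbone():
                missing = [a for a in BACKBONE_ATOMS if a not in r.atoms]
                raise MissingBackboneAtomError(
                    f"residue {r.name}{r.number} lacks backbone atom(s) "
                    f"{','.join(missing)}"
                )
            for name, xyz in r.atoms.items():
                if not np.all(np.isfinite(xyz)):
                    raise StructIOError(
                        f"non-finite coordinate for {name} in {r.name}{r.number}"
                    )
            if prev is not None and r.number <= prev:
                raise StructIOError(
                    f"residue numbers not strictly increasing at {r.number}"
                )
            prev = r.number


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # Highest occupancy wins; ties broken by alphabetically first altloc.
    return min(atoms, key=lambda a: (-a.occ, a.altloc))


def read_pdb(path, chain: str | None = None) -> BackboneStructure:
    """Read one chain of a PDB file into a :class:`BackboneStructure`.

    HETATM records on the same chain are stored in ``hetero_atoms``.
    ``chain`` may be omitted when the file holds a single chain.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0 or all(len(ch) == 0 for ch in st[0]):
        raise EmptyStructureError(f"{path} contains no ATOM records")
    model = st[0]
    names = [ch.name for ch in model]
    if chain is None:
        if len(set(names)) > 1:
            raise SelectionError(
                f"{path} has chains {sorted(set(names))}; specify one"
            )
        chain = names[0]
    elif chain not in names:
        raise SelectionError(f"chain {chain!r} not in {path} (has {names})")

    residues: list[Residue] = []
    hetero: list[tuple[str, str, np.ndarray]] = []
    keyed: list[tuple[tuple[int, str], Residue]] = []
    for ch in model:
        if ch.name != chain:
            continue
        for res in ch:
            is_het = res.het_flag == "H"
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            if is_het:
                for name in by_name:
                    a = _pick_altloc(by_name[name])
                    hetero.append(
                        (res.name, name, np.array([a.pos.x, a.pos.y, a.pos.z]))
                    )
                continue
            r = Residue(res.name, res.seqid.num)
            for name in by_name:
                a = _pick_altloc(by_name[name])
                r.atoms[name] = np.array([a.pos.x, a.pos.y, a.pos.z])
            keyed.append(((res.seqid.num, res.seqid.icode or " "), r))
    keyed.sort(key=lambda kr: kr[0])
    residues = [r for _, r in keyed]
    if not residues and not hetero:
        raise EmptyStructureError(f"chain {chain} of {path} is empty")
    out = BackboneStructure(residues, hetero, chain)
    out.validate()
    return out


def _pdb_atom_name(name: str) -> str:
    return f" {name:<3s}" if len(name) < 4 else name


def _element_of(name: str) -> str:
    stripped = name.lstrip("0123456789")
    return stripped[0] if stripped else "X"


def write_pdb(structure: BackboneStructure, path) -> None:
    """Write ATOM/HETATM/TER records; deterministic fixed-width output."""
    lines = []
    serial = 1
    order = ("N", "CA", "C", "O", "CB")
    for r in structure.residues:
        names = [a for a in order if a in r.atoms]
        names += sorted(a for a in r.atoms if a not in order)
        for name in names:
            x, y, z = r.atoms[name]
            lines.append(
                f"ATOM  {serial:>5d} {_pdb_atom_name(name)} {r.name:>3s} "
                f"{structure.chain_id:1s}{r.number:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {_element_of(name):>2s}"
            )
            serial += 1
    if structure.residues:
        last = structure.residues[-1]
        lines.append(
            f"TER   {serial:>5d}      {last.name:>3s} "
            f"{structure.chain_id:1s}{last.number:>4d}"
        )
        serial += 1
    het_num = (structure.residues[-1].number + 1) if structure.residues else 1
    for group, name, xyz in structure.hetero_atoms:
        x, y, z = xyz
        lines.append(
            f"HETATM{serial:>5d} {_pdb_atom_name(name)} {group:>3s} "
            f"{structure.chain_id:1s}{het_num:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {_element_of(name):>2s}"
        )
        serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def place_internal(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                   bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d given a–b–c–d dihedral, b–c–d angle and c–d bond.

    The natural-extension (NeRF) construction: d is ``bond`` Å from c,
    at planar angle ``angle_deg`` to b–c, with torsion ``dihedral_deg``
    about the b→c axis relative to a.
    """
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(chi),
            bond * math.sin(theta) * math.sin(chi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def reconstruct_cb(structure: BackboneStructure,
                   ideal: tuple[float, float, float] = IDEAL_CB) -> BackboneStructure:
    """Return a copy in which every residue carries a Cβ coordinate.

    Observed Cβ atoms of non-glycine residues are kept; glycines and
    residues without a Cβ get an ideal virtual Cβ placed from N/CA/C by
    the fixed internal coordinates in ``ideal``.
    """
    bond, angle, dihedral = ideal
    out = BackboneStructure([], list(structure.hetero_atoms), structure.chain_id)
    for r in structure.residues:
        if not r.has_backbone():
            missing = [a for a in BACKBONE_ATOMS if a not in r.atoms]
            raise MissingBackboneAtomError(
                f"residue {r.name}{r.number} lacks backbone atom(s) "
                f"{','.join(missing)}"
            )
        new = Residue(r.name, r.number, dict(r.atoms))
        if "CB" not in new.atoms or r.name == "GLY":
            # dihedral convention C–N–CA–CB, angle N–CA–CB, bond CA–CB
            new.atoms["CB"] = place_internal(
                r.atoms["C"], r.atoms["N"], r.atoms["CA"], bond, angle, dihedral
            )
        out.residues.append(new)
    return out


def residue_count(structure: BackboneStructure) -> int:
    """Number of polymer residues (hetero groups excluded)."""
    return len(structure.residues)


def one_letter_sequence(structure: BackboneStructure) -> str:
    """1-letter sequence of the polymer residues."""
    letters = []
    for r in structure.residues:
        if r.name not in THREE_TO_ONE:
            raise UnknownResidueError(f"non-standard residue {r.name}{r.number}")
        letters.append(THREE_TO_ONE[r.name])
    return "".join(letters)


def chain_mass(sequence: str) -> float:
    """Average-isotopic mass in Da of a free chain: residue masses + one water."""
    if not sequence:
        raise StructIOError("empty sequence has no mass")
    total = WATER_MASS
    for letter in sequence:
        if letter not in RESIDUE_MASS:
            raise UnknownResidueError(f"unknown amino-acid letter {letter!r}")
        total += RESIDUE_MASS[letter]
    return total


def _resolve(structure: BackboneStructure, selection) -> np.ndarray:
    key, atom_name = selection
    if isinstance(key, (int, np.integer)):
        hits = [
            r.atoms[atom_name]
            for r in structure.residues
            if r.number == int(key) and atom_name in r.atoms
        ]
    else:
        hits = [
            xyz
            for group, name, xyz in structure.hetero_atoms
            if group == key and name == atom_name
        ]
    if not hits:
        raise SelectionError(f"selection {selection!r} matches no atom")
    if len(hits) > 1:
        raise SelectionError(f"selection {selection!r} is ambiguous ({len(hits)} atoms)")
    return hits[0]


def atom_distance(structure: BackboneStructure, selection_a, selection_b) -> float:
    """Euclidean distance in Å between two uniquely selected atoms.

    A selection is ``(residue_number, atom_name)`` for polymer atoms or
    ``(group_name, atom_name)`` for hetero-group atoms, e.g.
    ``(65, "CZ")`` vs ``("DTZ", "N1")``.
    """
    a = _resolve(structure, selection_a)
    b = _resolve(structure, selection_b)
    return float(np.linalg.norm(a - b))
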
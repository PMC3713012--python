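"""Molecular structure I/O, atomic parameter assignment and RMSD.

Structures are read from PDB text (``ATOM``/``HETATM`` records), including
dock4-style files where several binding modes are concatenated and separated
by ``MODEL``/``ENDMDL``/``END``/``TER`` boundaries.  All structures handled
here are assumed to live in one common (already superposed) reference frame,
so RMSD is computed *without* re-superposition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Molecule",
    "ParameterTable",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "assign_parameters",
    "rmsd",
    "BACKBONE_ATOMS",
]

#: Atom names making up the peptide backbone selection.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Element-based van der Waals radii (Å), Bondi-style defaults.
ELEMENT_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}
DEFAULT_RADIUS = 1.70


class PDBParseError(ValueError):
    """Raised when a PDB record cannot be interpreted."""


@dataclass(frozen=True)
class Atom:
    """A single atom with coordinates and (optional) grid parameters."""

    element: str
    name: str
    residue_name: str
    residue_index: int
    chain_id: str
    coords: tuple[float, float, float]
    vdw_radius: float = DEFAULT_RADIUS
    partial_charge: float = 0.0

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.vdw_radius <= 0:
            raise ValueError(f"vdw_radius must be > 0, got {self.vdw_radius}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class Molecule:
    """An ordered collection of atoms sharing one superposition frame."""

    id: str
    atoms: list[Atom] = field(default_factory=list)
    sequence: str = ""
    frame_tag: str = "default"

    def __len__(self) -> int:
        return len(self.atoms)

    def coordinates(self, heavy_only: bool = False) -> np.ndarray:
        """Return an (n, 3) coordinate array, optionally heavy atoms only."""
        atoms = self.heavy_atoms() if heavy_only else self.atoms
        if not atoms:
            return np.empty((0, 3))
        return np.array([a.coords for a in atoms], dtype=float)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)


class ParameterTable:
    """Lookup of per-(residue, atom) van der Waals radii and partial charges.

    Unmatched atoms fall back to an element-based radius and zero charge; the
    fallbacks are counted so callers can report how much of a molecule was
    parameterised from defaults.
    """

    def __init__(
        self,
        entries: dict[tuple[str, str], tuple[float, float]] | None = None,
        element_radii: dict[str, float] | None = None,
    ) -> None:
        self.entries = {
            (rn.upper(), an.upper()): (float(r), float(q))
            for (rn, an), (r, q) in (entries or {}).items()
        }
        self.element_radii = {
            k.upper(): float(v) for k, v in (element_radii or ELEMENT_RADII).items()
        }

    @classmethod
    def from_csv(cls, path: str | Path) -> "ParameterTable":
        """Load a table from CSV columns residue_name, atom_name, radius, charge."""
        df = pd.read_csv(path)
        required = {"residue_name", "atom_name", "radius", "charge"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"parameter CSV missing columns: {sorted(missing)}")
        entries = {
            (str(row.residue_name), str(row.atom_name)): (row.radius, row.charge)
            for row in df.itertuples()
        }
        return cls(entries)

    def lookup(self, atom: Atom) -> tuple[float, float, bool]:
        """Return (radius, charge, was_defaulted) for *atom*.

        Exact (residue, atom) entries win; a residue of ``*`` in the table
        matches any residue for that atom name.
        """
        for key in (
            (atom.residue_name.upper(), atom.name.upper()),
            ("*", atom.name.upper()),
        ):
            if key in self.entries:
                r, q = self.entries[key]
                return r, q, False
        radius = self.element_radii.get(atom.element.upper(), DEFAULT_RADIUS)
        return radius, 0.0, True


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return "C"
    if name[0].isdigit():  # e.g. "1HB"
        name = name.lstrip("0123456789")
    if name[:2].upper() in ("CL", "BR"):
        return name[:2].upper()
    return name[0].upper()


def _parse_atom_record(line: str, lineno: int) -> Atom:
    try:
        name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21:22].strip() or "A"
        residue_index = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM record at line {lineno}: {line.rstrip()!r}") from exc
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element:
        element = _guess_element(name)
    return Atom(
        element=element,
        name=name,
        residue_name=residue_name,
        residue_index=residue_index,
        chain_id=chain_id,
        coords=(x, y, z),
    )


def read_pdb(path: str | Path, model_index: int | None = None, frame_tag: str = "default") -> list[Molecule]:
    """Parse a (possibly concatenated, dock4-style) PDB file into molecules.

    Entries are split on ``MODEL``/``ENDMDL``/``END`` boundaries; ids are
    taken from ``MODEL`` serials or ``REMARK  Name`` / ``COMPND`` lines when
    present, else they are sequential.  Coordinates are passed through
    unchanged.  ``model_index`` (0-based) selects one entry.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise PDBParseError(f"empty PDB file: {path}")

    molecules: list[Molecule] = []
    current_atoms: list[Atom] = []
    current_id: str | None = None

    def flush() -> None:
        nonlocal current_atoms, current_id
        if current_atoms:
            mol_id = current_id if current_id is not None else str(len(molecules) + 1)
            molecules.append(Molecule(id=mol_id, atoms=current_atoms, frame_tag=frame_tag))
        current_atoms = []
        current_id = None

    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6].strip().upper()
        if record in ("ATOM", "HETATM"):
            current_atoms.append(_parse_atom_record(line, lineno))
        elif record == "MODEL":
            flush()
            serial = line[6:].strip()
            current_id = serial or None
        elif record in ("ENDMDL", "END"):
            flush()
        elif record == "COMPND" and current_id is None:
            name = line[6:].strip()
            if name:
                current_id = name
        elif record == "REMARK":
            body = line[6:].strip()
            if body.lower().startswith("name"):
                parts = body.split(None, 1)
                if len(parts) > 1:  # an explicit name beats the MODEL serial
                    current_id = parts[1]
    flush()

    if not molecules:
        raise PDBParseError(f"no ATOM/HETATM records found in {path}")
    if model_index is not None:
        try:
            return [molecules[model_index]]
        except IndexError:
            raise IndexError(
                f"model_index {model_index} out of range for {len(molecules)} entries"
            ) from None
    return molecules


def write_pdb(molecules: Iterable[Molecule] | Molecule, path: str | Path) -> None:
    """Write molecules as concatenated MODEL/ENDMDL blocks (PDB precision)."""
    if isinstance(molecules, Molecule):
        molecules = [molecules]
    lines: list[str] = []
    for i, mol in enumerate(molecules, start=1):
        lines.append(f"MODEL {i:>8}")
        lines.append(f"REMARK Name {mol.id}")
        for serial, a in enumerate(mol.atoms, start=1):
            name = a.name if len(a.name) >= 4 else f" {a.name:<3}"
            lines.append(
                f"ATOM  {serial:>5} {name:<4}{a.residue_name:>4}"
                f" {a.chain_id:1}{a.residue_index:>4}    "
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def assign_parameters(mol: Molecule, table: ParameterTable) -> tuple[Molecule, int]:
    """Return a copy of *mol* with radii/charges set; also the defaulted count."""
    new_atoms: list[Atom] = []
    n_defaulted = 0
    for atom in mol.atoms:
        radius, charge, defaulted = table.lookup(atom)
        if defaulted:
            n_defaulted += 1
        new_atoms.append(replace(atom, vdw_radius=radius, partial_charge=charge))
    if n_defaulted:
        logger.warning(
            "%d/%d atoms of %s parameterised from element defaults (charge 0)",
            n_defaulted, len(mol.atoms), mol.id,
        )
    return Molecule(id=mol.id, atoms=new_atoms, sequence=mol.sequence, frame_tag=mol.frame_tag), n_defaulted


def _select_atoms(mol: Molecule, selection: str) -> dict[tuple[str, int, str], Atom]:
    """Map (chain, residue_index, atom_name) -> Atom for the given selection.

    Selections: ``all`` | ``backbone`` | ``heavy`` | ``heavy-excluding:<CHAIN>:<RESIDX>``
    (the last drops side-chain atoms beyond CB at the named residue).
    """
    if selection == "all":
        atoms = mol.atoms
    elif selection == "backbone":
        atoms = [a for a in mol.atoms if a.name.upper() in BACKBONE_ATOMS]
    elif selection == "heavy":
        atoms = mol.heavy_atoms()
    elif selection.startswith("heavy-excluding:"):
        _, chain, residx = selection.split(":")
        residx = int(residx)
        keep = set(BACKBONE_ATOMS) | {"CB"}
        atoms = [
            a
            for a in mol.heavy_atoms()
            if not (a.chain_id == chain and a.residue_index == residx and a.name.upper() not in keep)
        ]
    else:
        raise ValueError(f"unknown selection spec: {selection!r}")
    return {(a.chain_id, a.residue_index, a.name.upper()): a for a in atoms}


def rmsd(
    mol_a: Molecule,
    mol_b: Molecule,
    selection: str = "heavy",
    pair_by: str = "name",
) -> float:
    """RMSD between two superposed molecules, without re-fitting.

    Atoms are paired by (chain, residue_index, atom_name) when
    ``pair_by='name'``; ``pair_by='position'`` pairs the i-th selected atom of
    each molecule (useful across different residue types).  Raises if the
    selections cannot be fully paired.
    """
    if mol_a.frame_tag != mol_b.frame_tag:
        raise ValueError(
            f"molecules are in different frames: {mol_a.frame_tag!r} vs {mol_b.frame_tag!r}"
        )
    sel_a = _select_atoms(mol_a, selection)
    sel_b = _select_atoms(mol_b, selection)
    if pair_by == "name":
        keys = sorted(sel_a)
        missing = [k for k in keys if k not in sel_b]
        extra = [k for k in sel_b if k not in sel_a]
        if missing or extra:
            raise ValueError(
                f"unpairable selections: missing in B {missing[:5]}, missing in A {extra[:5]}"
            )
        pa = np.array([sel_a[k].coords for k in keys])
        pb = np.array([sel_b[k].coords for k in keys])
    elif pair_by == "position":
        atoms_a = sorted(sel_a.items())
        atoms_b = sorted(sel_b.items())
        if len(atoms_a) != len(atoms_b):
            raise ValueError(
                f"selections differ in length: {len(atoms_a)} vs {len(atoms_b)}"
            )
        pa = np.array([a.coords for _, a in atoms_a])
        pb = np.array([a.coords for _, a in atoms_b])
    else:
        raise ValueError(f"unknown pair_by: {pair_by!r}")
    if pa.size == 0:
        raise ValueError("empty selection")
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))
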
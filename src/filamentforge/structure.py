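"""Atomic structure data model and fixed-width PDB I/O.

The package works at a reduced per-nucleotide resolution (P, O3', C1',
N9/N1, base-centroid pseudo-atom), so the container is deliberately small:
an ordered atom list with chain/residue organisation, a chain-to-role map
annotating the three DNA strands of a strand-exchange intermediate, and a
free-form metadata dictionary that builders use to record pairing tables
and junction tags.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

INITIATING = "initiating"
COMPLEMENTARY = "complementary"
OUTGOING = "outgoing"
SCAFFOLD = "scaffold"
ROLES = (INITIATING, COMPLEMENTARY, OUTGOING, SCAFFOLD)
NUCLEIC_ROLES = (INITIATING, COMPLEMENTARY, OUTGOING)


class PDBParseError(ValueError):
    """Raised when a fixed-width ATOM/HETATM record cannot be parsed."""


@dataclasses.dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    residue_index: int
    residue_name: str
    chain_id: str

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom position must be a 3-vector, got {self.position.shape}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1")
        if not self.name:
            raise ValueError("atom name must be non-empty")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.position.copy(),
                    self.residue_index, self.residue_name, self.chain_id)


class Structure:
    """Ordered atom collection with strand-role annotation."""

    def __init__(self, atoms: Iterable[Atom], roles: Mapping[str, str] | None = None,
                 metadata: dict | None = None):
        self.atoms: list[Atom] = list(atoms)
        self.roles: dict[str, str] = dict(roles or {})
        self.metadata: dict = dict(metadata or {})
        for chain, role in self.roles.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for chain {chain!r}")

    # -- basic access -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for atom in self.atoms:
            seen.setdefault(atom.chain_id, None)
        return list(seen)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(len(self.atoms), 3)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        out = self.copy()
        for atom, pos in zip(out.atoms, coords):
            atom.position = pos.copy()
        return out

    def copy(self) -> "Structure":
        return Structure((a.copy() for a in self.atoms), self.roles, _deep_copy(self.metadata))

    def select(self, chain_id: str | None = None, name: str | None = None,
               residues: Sequence[int] | None = None) -> "Structure":
        residue_set = set(residues) if residues is not None else None
        picked = [a for a in self.atoms
                  if (chain_id is None or a.chain_id == chain_id)
                  and (name is None or a.name == name)
                  and (residue_set is None or a.residue_index in residue_set)]
        roles = {c: r for c, r in self.roles.items()
                 if chain_id is None or c == chain_id}
        return Structure((a.copy() for a in picked), roles, _deep_copy(self.metadata))

    def atom(self, chain_id: str, residue_index: int, name: str) -> Atom:
        for a in self.atoms:
            if a.chain_id == chain_id and a.residue_index == residue_index and a.name == name:
                return a
        raise KeyError(f"no atom {name!r} in {chain_id}:{residue_index}")

    def residue_indices(self, chain_id: str) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            if a.chain_id == chain_id:
                seen.setdefault(a.residue_index, None)
        return list(seen)

    def atom_positions(self, chain_id: str, name: str = "P",
                       residues: Sequence[int] | None = None) -> np.ndarray:
        """Positions of one named atom per residue, in residue order."""
        order = residues if residues is not None else self.residue_indices(chain_id)
        table = {(a.residue_index): a.position for a in self.atoms
                 if a.chain_id == chain_id and a.name == name}
        missing = [r for r in order if r not in table]
        if missing:
            raise KeyError(f"chain {chain_id}: residue(s) {missing} lack atom {name!r}")
        return np.array([table[r] for r in order], dtype=float)

    def chain_role(self, role: str) -> str:
        matches = [c for c, r in self.roles.items() if r == role]
        if len(matches) != 1:
            raise KeyError(f"expected exactly one chain with role {role!r}, found {matches}")
        return matches[0]

    def validate(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_index, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key}")
            seen.add(key)
        atom_chains = set(c for c in self.chains())
        for chain in self.roles:
            if chain not in atom_chains:
                raise ValueError(f"role assigned to absent chain {chain!r}")


def _deep_copy(obj):
    if isinstance(obj, dict):
        return {k: _deep_copy(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return type(obj)(_deep_copy(v) for v in obj)
    if isinstance(obj, np.ndarray):
        return obj.copy()
    return obj


def concatenate(parts: Sequence[Structure], metadata: dict | None = None) -> Structure:
    atoms: list[Atom] = []
    roles: dict[str, str] = {}
    for part in parts:
        atoms.extend(a.copy() for a in part.atoms)
        roles.update(part.roles)
    return Structure(atoms, roles, metadata or {})


# -- role annotation --------------------------------------------------------

def annotate_roles(structure: Structure, assignment: Mapping[str, str],
                   strict: bool = False) -> Structure:
    """Return a copy with chain roles updated.

    With ``strict=True`` each nucleic role may appear on at most one chain,
    which is the situation in a complete synaptic model (one initiating,
    one complementary, one outgoing strand).
    """
    chains = set(structure.chains())
    for chain in assignment:
        if chain not in chains:
            raise KeyError(f"cannot annotate absent chain {chain!r}")
    for role in assignment.values():
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
    out = structure.copy()
    out.roles.update(assignment)
    if strict:
        for role in NUCLEIC_ROLES:
            holders = [c for c, r in out.roles.items() if r == role]
            if len(holders) > 1:
                raise ValueError(f"role {role!r} assigned to multiple chains {holders}")
    return out


# -- fixed-width PDB codec --------------------------------------------------

_RESNAME_1TO3 = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}


def read_pdb(path: str | Path) -> Structure:
    """Parse standard fixed-width ATOM/HETATM records into a Structure.

    Record order is preserved; roles default to scaffold for every chain
    until annotated.  A malformed record raises :class:`PDBParseError`
    naming the offending line.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc
    atoms: list[Atom] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        record = line[:6].strip()
        if record not in ("ATOM", "HETATM"):
            continue
        if len(line) < 54:
            raise PDBParseError(f"{path}:{lineno}: truncated {record} record")
        try:
            name = line[12:16].strip()
            res_name = line[17:20].strip()
            chain_id = line[21].strip() or "A"
            res_index = int(line[22:26])
            position = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
        except ValueError as exc:
            raise PDBParseError(f"{path}:{lineno}: malformed fixed-width field: {exc}") from exc
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = name[:1]
        atoms.append(Atom(name, element, np.array(position), res_index, res_name, chain_id))
    if not atoms:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    structure = Structure(atoms, {chain: SCAFFOLD for chain in {a.chain_id for a in atoms}})
    structure.roles = {c: SCAFFOLD for c in structure.chains()}
    return structure


def write_pdb(structure: Structure, path: str | Path) -> Path:
    """Emit fixed-width v3.3 ATOM records, one TER per chain, then END."""
    if not structure.atoms:
        raise ValueError("refusing to write an empty structure")
    path = Path(path)
    lines: list[str] = []
    serial = 0
    chains = structure.chains()
    for chain in chains:
        last_atom = None
        for atom in structure.atoms:
            if atom.chain_id != chain:
                continue
            serial += 1
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            x, y, z = atom.position
            if max(abs(x), abs(y), abs(z)) >= 1e4 or not math.isfinite(x + y + z):
                raise ValueError(f"coordinate out of PDB fixed-width range for atom {atom.name}")
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} {atom.residue_name:>3s} {chain:1s}"
                f"{atom.residue_index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
            )
            last_atom = atom
        serial += 1
        lines.append(f"TER   {serial:5d}      {last_atom.residue_name:>3s} "
                     f"{chain:1s}{last_atom.residue_index:4d}")
    lines.append("END")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write PDB file {path}: {exc}") from exc
    return path
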
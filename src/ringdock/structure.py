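"""Molecular structures and truncated active-site models.

Reads receptor structures from PDB, ligands from XYZ/SDF/PDB, and builds
frozen-heavy-atom active-site cluster models from explicit
``(residue_name, residue_number)`` selections.  All coordinates are
Cartesian Å throughout; no unit conversion happens anywhere downstream.

Protonation is the caller's responsibility: quantum-chemical backends
need explicit hydrogens, and so does the built-in surrogate scorer. The
engine itself accepts structures with or without hydrogens.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .data.radii import RADII_SETS

__all__ = [
    "Atom",
    "Molecule",
    "ActiveSiteModel",
    "read_pdb",
    "read_ligand",
    "read_xyz",
    "write_xyz",
    "write_pdb",
    "extract_active_site",
]


@dataclass
class Atom:
    """A single atom: element, position (Å) and residue bookkeeping.

    ``frozen`` marks atoms whose positions are held fixed in downstream
    refinement jobs (the receptor-heavy-atom convention); ``charge`` is
    an optional per-atom partial charge (e) consumed by the surrogate
    scorer, overriding its per-element default.
    """

    element: str
    coords: np.ndarray
    residue_name: str = ""
    residue_number: int | None = None
    atom_name: str = ""
    is_polar_hydrogen: bool = False
    frozen: bool = False
    het: bool = False
    charge: float | None = None

    def __post_init__(self) -> None:
        self.element = self.element.strip().capitalize()
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(
                f"atom {self.atom_name or self.element!r}: coordinates must be "
                f"a finite 3-vector, got {self.coords!r}"
            )
        if self.element.upper() not in RADII_SETS["bondi"]:
            raise ValueError(
                f"unknown element {self.element!r} for atom "
                f"{self.atom_name or '?'} (no van der Waals radius tabulated)"
            )
        if self.is_polar_hydrogen and not self.is_hydrogen:
            raise ValueError(
                f"atom {self.atom_name or self.element!r}: is_polar_hydrogen "
                "set on a non-hydrogen atom"
            )

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class Molecule:
    """An ordered collection of atoms; ``rigid`` ligands only ever move as
    rigid bodies (rotation + translation), preserving internal distances."""

    atoms: list[Atom]
    name: str = ""
    rigid: bool = False

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"molecule {self.name!r} has no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å (a copy)."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        """Return a copy of this molecule with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [replace(a, coords=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Molecule(atoms=atoms, name=self.name, rigid=self.rigid)


@dataclass
class ActiveSiteModel:
    """A truncated receptor model: the atoms of an explicit residue
    selection, with every heavy atom frozen."""

    atoms: list[Atom]
    residue_index: dict[int, list[int]] = field(default_factory=dict)
    source_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for num, idxs in self.residue_index.items():
            for i in idxs:
                if not (0 <= i < n):
                    raise ValueError(
                        f"residue {num}: atom index {i} out of range"
                    )
                if self.atoms[i].residue_number != num:
                    raise ValueError(
                        f"residue index inconsistent at residue {num}"
                    )

    @property
    def n_residues(self) -> int:
        return len(self.residue_index)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def residue_atoms(self, residue_number: int) -> list[Atom]:
        if residue_number not in self.residue_index:
            raise KeyError(f"residue {residue_number} not in active-site model")
        return [self.atoms[i] for i in self.residue_index[residue_number]]


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _prevalidate_pdb(path: Path) -> None:
    """Fail fast, naming the line, on malformed ATOM/HETATM records."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ValueError(
                    f"{path}, line {lineno}: ATOM/HETATM record too short "
                    "for coordinate fields"
                )
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise ValueError(
                    f"{path}, line {lineno}: unparseable coordinates in "
                    f"record {line[:27].strip()!r}"
                ) from exc


def read_pdb(path: str | Path) -> list[Molecule]:
    """Read a fixed-column PDB file into one :class:`Molecule` per chain.

    Residue names/numbers are preserved exactly; insertion codes are
    appended to the residue name tag.  HETATM atoms carry ``het=True``.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate_pdb(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    st.setup_entities()
    molecules: list[Molecule] = []
    for model in st:
        for chain in model:
            atoms: list[Atom] = []
            for residue in chain:
                het = residue.het_flag == "H"
                icode = residue.seqid.icode.strip()
                rname = residue.name + (icode if icode else "")
                for at in residue:
                    elem = at.element.name
                    if elem in ("", "X"):
                        raise ValueError(
                            f"{path}: unknown element for atom "
                            f"{at.name!r} in residue {rname}{residue.seqid.num}"
                        )
                    atoms.append(
                        Atom(
                            element=elem,
                            coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                            residue_name=rname,
                            residue_number=residue.seqid.num,
                            atom_name=at.name,
                            het=het,
                        )
                    )
            if atoms:
                molecules.append(Molecule(atoms=atoms, name=chain.name))
        break  # first model only
    if not molecules:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    return molecules


def write_pdb(molecules: Molecule | ActiveSiteModel | Sequence[Molecule],
              path: str | Path, *, remark: str = "") -> None:
    """Write molecules (or an active-site model) as fixed-column PDB."""
    if isinstance(molecules, (Molecule, ActiveSiteModel)):
        groups: list[tuple[str, list[Atom]]] = [("A", list(molecules.atoms))]
    else:
        chain_ids = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        groups = [
            (chain_ids[i % len(chain_ids)], list(m.atoms))
            for i, m in enumerate(molecules)
        ]
    lines: list[str] = []
    if remark:
        lines.append(f"REMARK   1 {remark}")
    serial = 1
    for chain_id, atoms in groups:
        for a in atoms:
            record = "HETATM" if a.het else "ATOM  "
            name = a.atom_name or a.element
            # PDB convention: 1-char elements start at column 14
            name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
            resname = (a.residue_name or "UNK")[:3]
            resnum = a.residue_number if a.residue_number is not None else 1
            x, y, z = a.coords
            lines.append(
                f"{record}{serial:>5d} {name_field} {resname:>3s} {chain_id}"
                f"{resnum:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element.upper():>2s}"
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path) -> Molecule:
    """Read an XYZ file (count line, comment line, ``element x y z`` rows)."""
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise ValueError(f"{path}: empty XYZ file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: XYZ header is not an atom count") from exc
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) != count:
        raise ValueError(
            f"{path}: XYZ header declares {count} atoms but file has "
            f"{len(body)} coordinate lines"
        )
    name = lines[1].strip() if len(lines) > 1 else ""
    atoms = []
    for ln in body:
        parts = ln.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: malformed XYZ coordinate line {ln!r}")
        atoms.append(Atom(element=parts[0], coords=[float(p) for p in parts[1:4]]))
    return Molecule(atoms=atoms, name=name or path.stem)


def write_xyz(mol: Molecule | ActiveSiteModel, path: str | Path,
              *, comment: str | None = None) -> None:
    atoms = mol.atoms
    name = comment if comment is not None else getattr(mol, "name", "")
    lines = [str(len(atoms)), name]
    for a in atoms:
        x, y, z = a.coords
        lines.append(f"{a.element:<2s} {x:15.6f} {y:15.6f} {z:15.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Ligand reading
# ---------------------------------------------------------------------------

def read_ligand(path: str | Path, format: str | None = None) -> Molecule:
    """Read a rigid ligand from XYZ, SDF (V2000) or PDB.

    The engine needs only elements and coordinates; bonds are not used.
    The returned molecule has ``rigid=True``.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        mol = read_xyz(path)
    elif fmt in ("sdf", "mol"):
        mol = _read_sdf(path)
    elif fmt in ("pdb", "ent"):
        chains = read_pdb(path)
        atoms = [a for m in chains for a in m.atoms]
        mol = Molecule(atoms=atoms, name=path.stem)
    else:
        raise ValueError(f"unsupported ligand format {fmt!r} for {path}")
    mol.rigid = True
    return mol


def _read_sdf(path: Path) -> Molecule:
    from rdkit import Chem

    rd = Chem.MolFromMolFile(str(path), removeHs=False, sanitize=False)
    if rd is None:
        raise ValueError(f"cannot parse SDF/MOL file {path}")
    conf = rd.GetConformer()
    atoms = []
    for i, at in enumerate(rd.GetAtoms()):
        pos = conf.GetAtomPosition(i)
        atoms.append(Atom(element=at.GetSymbol(), coords=[pos.x, pos.y, pos.z]))
    return Molecule(atoms=atoms, name=path.stem)


# ---------------------------------------------------------------------------
# Active-site extraction
# ---------------------------------------------------------------------------

def extract_active_site(
    structure: Molecule | Sequence[Molecule],
    residues: Iterable[tuple[str, int]],
    *,
    source_id: str = "",
) -> ActiveSiteModel:
    """Build a frozen-heavy-atom cluster model from a residue selection.

    Each requested residue is a ``(name, number)`` pair; the name must
    match the structure at that number (guarding against renumbered
    files).  The result is independent of the order of ``residues``.
    """
    wanted = [(name.strip().upper(), int(num)) for name, num in residues]
    if not wanted:
        raise ValueError("empty selection: no residues requested")
    if len({num for _, num in wanted}) != len(wanted):
        raise ValueError("duplicate residue numbers in selection")

    if isinstance(structure, Molecule):
        all_atoms = list(structure.atoms)
    else:
        all_atoms = [a for m in structure for a in m.atoms]

    by_number: dict[int, list[Atom]] = {}
    for a in all_atoms:
        if a.residue_number is not None:
            by_number.setdefault(a.residue_number, []).append(a)

    atoms: list[Atom] = []
    residue_index: dict[int, list[int]] = {}
    for name, num in sorted(wanted, key=lambda t: t[1]):
        group = by_number.get(num)
        if not group:
            raise KeyError(f"residue {name}{num} not found in structure")
        found_names = {a.residue_name.strip().upper() for a in group}
        if name not in found_names:
            raise ValueError(
                f"residue number {num} is {'/'.join(sorted(found_names))} in "
                f"the structure, not {name} as requested (renumbered file?)"
            )
        start = len(atoms)
        for a in group:
            if a.residue_name.strip().upper() != name:
                continue
            atoms.append(replace(a, frozen=not a.is_hydrogen))
        residue_index[num] = list(range(start, len(atoms)))
    return ActiveSiteModel(atoms=atoms, residue_index=residue_index,
                           source_id=source_id)
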
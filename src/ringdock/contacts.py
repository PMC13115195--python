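"""Automated ligand–residue interaction-distance analysis.

For each contact specification the minimum distance between selected
ligand atoms and selected atoms of a named receptor residue is
reported, labelled ``ligand_element⋯residue_element``.  A contact is
flagged *strong* when the distance falls at or below a cutoff
(default 3.2 Å) **and** both partners are plausible polar partners
(N/O/S/P heteroatoms, or a polar hydrogen).  Distances are computed on
heavy atoms unless a selector names hydrogens explicitly; no angular
hydrogen-bond criterion is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from fnmatch import fnmatch
from typing import Sequence

import numpy as np
import pandas as pd

from .structure import ActiveSiteModel, Atom, Molecule

__all__ = ["ContactSpec", "ContactRow", "min_distance", "contact_table",
           "POLAR_ELEMENTS"]

POLAR_ELEMENTS = {"N", "O", "S", "P"}


@dataclass(frozen=True)
class ContactSpec:
    """Selects a ligand-atom set and a residue-atom set to measure.

    ``residue_atom_selector`` is a PDB atom-name glob (e.g. ``OG``,
    ``N*``) or ``"any"``; ``ligand_atom_selector`` is an element symbol,
    an integer atom index, or ``"any"``.
    """

    residue: tuple[str, int]
    residue_atom_selector: str = "any"
    ligand_atom_selector: str | int = "any"
    strong_cutoff: float = 3.2

    def __post_init__(self) -> None:
        if self.strong_cutoff <= 0:
            raise ValueError("strong_cutoff must be positive")


@dataclass(frozen=True)
class ContactRow:
    """One measured contact: label like ``"N⋯O"`` (ligand⋯residue),
    minimum distance in Å, and the strong-interaction flag."""

    residue: str
    label: str
    distance: float
    strong: bool

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


def _is_polar_partner(atom: Atom) -> bool:
    if atom.is_hydrogen:
        return atom.is_polar_hydrogen
    return atom.element.upper() in POLAR_ELEMENTS


def _select_ligand_atoms(ligands: Sequence[Molecule],
                         selector: str | int) -> list[Atom]:
    atoms = [a for lig in ligands for a in lig.atoms]
    if isinstance(selector, int):
        if not (0 <= selector < len(atoms)):
            raise ValueError(f"ligand atom index {selector} out of range")
        return [atoms[selector]]
    sel = selector.strip()
    if sel.lower() == "any":
        chosen = [a for a in atoms if not a.is_hydrogen]
        return chosen or atoms
    explicit_h = sel.upper() == "H"
    chosen = [a for a in atoms if a.element.upper() == sel.upper()]
    if not chosen:
        raise ValueError(f"ligand selector {selector!r} matches no atom")
    if not explicit_h:
        heavy = [a for a in chosen if not a.is_hydrogen]
        chosen = heavy or chosen
    return chosen


def _select_residue_atoms(receptor: ActiveSiteModel,
                          spec: ContactSpec) -> list[Atom]:
    name, number = spec.residue
    if number not in receptor.residue_index:
        raise KeyError(f"residue {name}{number} not in receptor model")
    atoms = receptor.residue_atoms(number)
    found = {a.residue_name.strip().upper() for a in atoms}
    if name.strip().upper() not in found:
        raise ValueError(
            f"residue {number} is {'/'.join(sorted(found))}, not {name}"
        )
    sel = spec.residue_atom_selector.strip()
    if sel.lower() == "any":
        chosen = [a for a in atoms if not a.is_hydrogen]
        return chosen or atoms
    explicit_h = sel.upper().startswith("H")
    chosen = [a for a in atoms if fnmatch(a.atom_name.strip().upper(),
                                          sel.upper())]
    if not chosen:
        raise ValueError(
            f"residue atom selector {spec.residue_atom_selector!r} matches "
            f"no atom in {name}{number}"
        )
    if not explicit_h:
        heavy = [a for a in chosen if not a.is_hydrogen]
        chosen = heavy or chosen
    return chosen


def min_distance(receptor: ActiveSiteModel, ligands: Sequence[Molecule],
                 spec: ContactSpec) -> ContactRow:
    """Minimum distance over the cross product of the two selections."""
    lig_atoms = _select_ligand_atoms(ligands, spec.ligand_atom_selector)
    res_atoms = _select_residue_atoms(receptor, spec)
    lc = np.array([a.coords for a in lig_atoms])
    rc = np.array([a.coords for a in res_atoms])
    d = np.linalg.norm(lc[:, None, :] - rc[None, :, :], axis=-1)
    i, j = np.unravel_index(int(np.argmin(d)), d.shape)
    dist = float(d[i, j])
    la, ra = lig_atoms[i], res_atoms[j]
    strong = (dist <= spec.strong_cutoff
              and _is_polar_partner(la) and _is_polar_partner(ra))
    name, number = spec.residue
    return ContactRow(
        residue=f"{name.capitalize()}{number}",
        label=f"{la.element}⋯{ra.element}",
        distance=dist,
        strong=strong,
    )


def contact_table(receptor: ActiveSiteModel, ligands: Sequence[Molecule],
                  specs: Sequence[ContactSpec]) -> pd.DataFrame:
    """One row per contact spec, in order, as a DataFrame with columns
    residue / contact / distance_A / strong."""
    if not specs:
        raise ValueError("no contact specifications given")
    rows = [min_distance(receptor, ligands, s) for s in specs]
    return pd.DataFrame(
        {
            "residue": [r.residue for r in rows],
            "contact": [r.label for r in rows],
            "distance_A": [round(r.distance, 3) for r in rows],
            "strong": [r.strong for r in rows],
        }
    )
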
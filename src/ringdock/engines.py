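"""Adapters to external semi-empirical quantum-chemistry engines.

The protocol's production energies are PM7 heats of formation and
harmonic-frequency thermochemistry; those are never computed here.
Instead this module writes input decks and parses output files for two
dialects:

* ``mopac`` — MOPAC-style: keyword line, per-atom optimisation flags
  (1 = free, 0 = frozen), a ``FINAL HEAT OF FORMATION`` line and a
  thermochemistry block;
* ``gaussian`` — Gaussian-style: route section, frozen flags (−1 =
  frozen, 0 = free), ``SCF Done`` energies and ``Sum of electronic and
  thermal ...`` thermochemistry in Hartree.

The parser implements the minimal grammar of each dialect (final
energy, thermochemistry, termination marker), not a full log replay.
All values are converted to kJ mol⁻¹ at this boundary
(1 kcal = 4.184 kJ, 1 Hartree = 2625.4996 kJ mol⁻¹).

Frozen-atom convention for refinement jobs: receptor heavy atoms
frozen, receptor hydrogens free, ligand atoms fully free.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .structure import ActiveSiteModel, Atom, Molecule

__all__ = ["ThermoRecord", "write_input", "parse_output",
           "read_deck_geometry", "KCAL_TO_KJ", "HARTREE_TO_KJ"]

KCAL_TO_KJ = 4.184
HARTREE_TO_KJ = 2625.49963948
T_STANDARD = 298.15  # K; standard pressure 101 325 Pa (documentation only)

from .energy import EnergyResult  # noqa: E402  (shared result type)


@dataclass(frozen=True)
class ThermoRecord:
    """Formation thermochemistry of one species at T = 298.15 K:
    ΔfH°, the entropy contribution T·S (both kJ mol⁻¹) and ΔfG°."""

    species_id: str
    dHf: float
    TdS: float | None = None
    dGf: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.dHf):
            raise ValueError(f"{self.species_id}: non-finite dHf")
        if self.TdS is not None and self.dGf is not None:
            if abs(self.dGf - (self.dHf - self.TdS)) > 0.02:
                raise ValueError(
                    f"{self.species_id}: inconsistent thermochemistry "
                    f"(dGf={self.dGf} != dHf - TdS = {self.dHf - self.TdS:.4f})"
                )


def _gather_atoms(complex_atoms) -> list[Atom]:
    if isinstance(complex_atoms, (Molecule, ActiveSiteModel)):
        return list(complex_atoms.atoms)
    atoms: list[Atom] = []
    for part in complex_atoms:
        atoms.extend(part.atoms)
    return atoms


def write_input(complex_atoms, task: str = "single_point",
                dialect: str = "mopac", *, title: str = "ringdock job",
                charge: int = 0) -> str:
    """Emit an input deck for one species.

    ``complex_atoms`` is a Molecule, an ActiveSiteModel, or a sequence of
    them (receptor first, then placed ligands).  For ``optimize+freq``
    each atom's ``frozen`` flag controls its optimisation flag; for
    ``single_point`` no atom is optimised.
    """
    if task not in ("single_point", "optimize+freq"):
        raise ValueError(f"unknown task {task!r}")
    atoms = _gather_atoms(complex_atoms)
    if dialect == "mopac":
        keywords = "PM7 1SCF" if task == "single_point" \
            else "PM7 EF THERMO(298.15K)"
        if charge:
            keywords += f" CHARGE={charge}"
        lines = [keywords, title, ""]
        for a in atoms:
            flag = 0 if (task == "single_point" or a.frozen) else 1
            x, y, z = a.coords
            lines.append(
                f"{a.element:<2s} {x:14.6f} {flag:d} {y:14.6f} {flag:d} "
                f"{z:14.6f} {flag:d}"
            )
        return "\n".join(lines) + "\n"
    if dialect == "gaussian":
        route = "#P PM7" if task == "single_point" else "#P PM7 Opt Freq"
        lines = [route, "", title, "", f"{charge} 1"]
        for a in atoms:
            x, y, z = a.coords
            if task == "single_point":
                lines.append(f" {a.element:<2s} {x:14.6f} {y:14.6f} {z:14.6f}")
            else:
                flag = -1 if a.frozen else 0
                lines.append(
                    f" {a.element:<2s} {flag:>2d} {x:14.6f} {y:14.6f} {z:14.6f}"
                )
        return "\n".join(lines) + "\n\n"
    raise ValueError(f"unknown engine dialect {dialect!r}")


def read_deck_geometry(text: str, dialect: str = "mopac"
                       ) -> tuple[list[str], np.ndarray, list[bool]]:
    """Parse back (elements, coords, free-flags) from an emitted deck."""
    elements: list[str] = []
    coords: list[list[float]] = []
    free: list[bool] = []
    if dialect == "mopac":
        for line in text.splitlines()[3:]:
            parts = line.split()
            if len(parts) != 7:
                continue
            elements.append(parts[0])
            coords.append([float(parts[1]), float(parts[3]), float(parts[5])])
            free.append(parts[2] == "1")
    elif dialect == "gaussian":
        for line in text.splitlines():
            parts = line.split()
            if len(parts) == 5 and parts[1] in ("-1", "0"):
                elements.append(parts[0])
                coords.append([float(p) for p in parts[2:5]])
                free.append(parts[1] == "0")
            elif len(parts) == 4 and re.fullmatch(r"[A-Z][a-z]?", parts[0]):
                elements.append(parts[0])
                coords.append([float(p) for p in parts[1:4]])
                free.append(True)
    else:
        raise ValueError(f"unknown engine dialect {dialect!r}")
    return elements, np.asarray(coords, dtype=float), free


_MOPAC_HOF = re.compile(
    r"FINAL HEAT OF FORMATION\s*=\s*(-?\d+(?:\.\d+)?)\s*(KCAL/MOL|KJ/MOL)"
    r"(?:\s*=\s*(-?\d+(?:\.\d+)?)\s*(KCAL/MOL|KJ/MOL))?"
)
_MOPAC_THERMO = {
    "dHf": re.compile(r"ENTHALPY OF FORMATION\s*=\s*(-?\d+(?:\.\d+)?)\s*(KCAL/MOL|KJ/MOL)"),
    "TdS": re.compile(r"T\W?DELTA\W?S(?: CONTRIBUTION)?\s*=\s*(-?\d+(?:\.\d+)?)\s*(KCAL/MOL|KJ/MOL)"),
    "dGf": re.compile(r"GIBBS (?:FREE )?ENERGY OF FORMATION\s*=\s*(-?\d+(?:\.\d+)?)\s*(KCAL/MOL|KJ/MOL)"),
}
_GAUSSIAN_SCF = re.compile(r"SCF Done:\s*E\([^)]*\)\s*=\s*(-?\d+(?:\.\d+)?(?:[DEde][+-]?\d+)?)")
_GAUSSIAN_H = re.compile(r"Sum of electronic and thermal Enthalpies=\s*(-?\d+\.\d+)")
_GAUSSIAN_G = re.compile(r"Sum of electronic and thermal Free Energies=\s*(-?\d+\.\d+)")


def _to_kj(value: float, unit: str) -> float:
    return value * KCAL_TO_KJ if unit.upper().startswith("KCAL") else value


def parse_output(text: str, dialect: str | None = None, *,
                 species_id: str = "species"
                 ) -> tuple[EnergyResult, ThermoRecord | None]:
    """Extract the final energy (kJ mol⁻¹) and, when present, a
    thermochemistry record from an engine output file.

    Dialect is auto-detected when not given.  A recognised output with
    no converged-termination marker yields ``converged=False`` (not an
    exception); an output with no final energy at all is an error.
    """
    if dialect is None:
        if "Gaussian" in text or _GAUSSIAN_SCF.search(text):
            dialect = "gaussian"
        else:
            dialect = "mopac"
    if dialect == "mopac":
        m = _MOPAC_HOF.search(text)
        if not m:
            raise ValueError("no final energy found in engine output "
                             "(truncated file?)")
        # prefer an explicitly kJ-printed field when both units appear
        value = _to_kj(float(m.group(1)), m.group(2))
        if m.group(3) and m.group(4) and m.group(4).upper().startswith("KJ"):
            value = float(m.group(3))
        converged = ("JOB ENDED NORMALLY" in text) or ("MOPAC DONE" in text)
        thermo = None
        fields: dict[str, float] = {}
        for key, rx in _MOPAC_THERMO.items():
            tm = rx.search(text)
            if tm:
                fields[key] = _to_kj(float(tm.group(1)), tm.group(2))
        if "dHf" in fields:
            thermo = ThermoRecord(species_id=species_id, dHf=fields["dHf"],
                                  TdS=fields.get("TdS"), dGf=fields.get("dGf"))
        return EnergyResult(value, "mopac", converged), thermo
    if dialect == "gaussian":
        scf = _GAUSSIAN_SCF.search(text)
        h = _GAUSSIAN_H.search(text)
        g = _GAUSSIAN_G.search(text)
        if not scf and not h:
            raise ValueError("no final energy found in engine output "
                             "(truncated file?)")
        converged = "Normal termination" in text
        thermo = None
        if h:
            h_kj = float(h.group(1)) * HARTREE_TO_KJ
            if g:
                g_kj = float(g.group(1)) * HARTREE_TO_KJ
                thermo = ThermoRecord(species_id=species_id, dHf=h_kj,
                                      TdS=h_kj - g_kj, dGf=g_kj)
            else:
                thermo = ThermoRecord(species_id=species_id, dHf=h_kj)
        if scf:
            energy = float(scf.group(1).replace("D", "E").replace("d", "e")) \
                * HARTREE_TO_KJ
        else:
            energy = thermo.dHf  # type: ignore[union-attr]
        return EnergyResult(energy, "gaussian", converged), thermo
    raise ValueError(f"unknown engine dialect {dialect!r}")
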
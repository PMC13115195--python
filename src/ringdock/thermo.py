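"""Standard binding thermodynamics and dual-ligand cooperativity.

For a docking event ``site + n·ligand → complex`` the binding quantity
of any formation property X (enthalpy, the T·S entropy contribution, or
Gibbs energy) is

    Δb X° = Δf X°(complex) − Δf X°(site) − n · Δf X°(ligand)

at T = 298.15 K and standard pressure 101 325 Pa (the pressure only
defines the standard state; nothing here consumes it).  Entropy is
carried throughout as the pre-multiplied T·S term in kJ mol⁻¹, matching
how thermochemistry tables are reported and avoiding a J-vs-kJ unit
trap.

Cooperativity of dual occupancy compares the two-ligand binding Gibbs
energy against the sum of the two single-ligand cluster values:
ΔΔG_coop = ΔbG°(dual) − [ΔbG°(cluster 1) + ΔbG°(cluster 2)];
negative means synergistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engines import ThermoRecord

__all__ = ["T_ROOM", "BindingThermo", "CooperativityReport", "binding_gibbs",
           "gibbs_from_H_TS", "binding_thermo", "cooperativity",
           "binding_table"]

T_ROOM = 298.15  # K


@dataclass(frozen=True)
class BindingThermo:
    """ΔbH°, T·ΔbS° and ΔbG° (kJ mol⁻¹) for one docking event."""

    dbH: float
    TdbS: float
    dbG: float
    n_ligands: int = 1

    def __post_init__(self) -> None:
        if abs(self.dbG - (self.dbH - self.TdbS)) > 0.02:
            raise ValueError(
                f"inconsistent binding thermodynamics: dbG={self.dbG} but "
                f"dbH - TdbS = {self.dbH - self.TdbS:.4f}"
            )
        if self.n_ligands < 1:
            raise ValueError("n_ligands must be >= 1")


@dataclass(frozen=True)
class CooperativityReport:
    """Dual-occupancy cooperativity: ΔΔG_coop = ΔbG°(dual) − ΔbG°(ref sum)."""

    dbG_dual: float
    dbG_ref_sum: float
    ddG_coop: float
    synergistic: bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.ddG_coop):
            raise ValueError("non-finite cooperativity")
        if self.synergistic != (self.ddG_coop < 0):
            raise ValueError("synergistic flag inconsistent with sign")


def binding_gibbs(dXf_complex: float, dXf_site: float, dXf_ligand: float,
                  n: int = 1) -> float:
    """ΔbX° = ΔfX°(complex) − ΔfX°(site) − n·ΔfX°(ligand).

    The same formula applies to enthalpies, T·S terms and Gibbs
    energies; ``n`` is the number of simultaneously docked copies.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return float(dXf_complex) - float(dXf_site) - n * float(dXf_ligand)


def gibbs_from_H_TS(dbH: float, TdbS: float) -> float:
    """ΔbG° = ΔbH° − T·ΔbS°, all at 298.15 K in kJ mol⁻¹."""
    return float(dbH) - float(TdbS)


def binding_thermo(complex_rec: ThermoRecord, site_rec: ThermoRecord,
                   ligand_rec: ThermoRecord, n: int = 1) -> BindingThermo:
    """Binding thermodynamics from three species thermochemistry records."""
    for rec in (complex_rec, site_rec, ligand_rec):
        if rec.TdS is None or rec.dGf is None:
            raise ValueError(
                f"species {rec.species_id!r} lacks entropy/Gibbs data "
                "(needs a frequency calculation)"
            )
    dbH = binding_gibbs(complex_rec.dHf, site_rec.dHf, ligand_rec.dHf, n)
    TdbS = binding_gibbs(complex_rec.TdS, site_rec.TdS, ligand_rec.TdS, n)
    dbG = binding_gibbs(complex_rec.dGf, site_rec.dGf, ligand_rec.dGf, n)
    return BindingThermo(dbH=dbH, TdbS=TdbS, dbG=dbG, n_ligands=n)


def cooperativity(dbG_dual: float, dbG_cluster1: float,
                  dbG_cluster2: float) -> CooperativityReport:
    """Compare dual-occupancy binding against the two single-ligand
    cluster values; negative ΔΔG_coop = synergistic binding."""
    ref = float(dbG_cluster1) + float(dbG_cluster2)
    ddg = float(dbG_dual) - ref
    return CooperativityReport(dbG_dual=float(dbG_dual), dbG_ref_sum=ref,
                               ddG_coop=ddg, synergistic=ddg < 0)


def binding_table(rows: Mapping[str, BindingThermo] |
                  Sequence[tuple[str, BindingThermo]]) -> pd.DataFrame:
    """Tabulate binding thermodynamics in the standard three-column
    layout (ΔbH°, T·ΔbS°, ΔbG°, kJ mol⁻¹), rounded to two decimals."""
    items = rows.items() if isinstance(rows, Mapping) else rows
    data = [
        {
            "species": name,
            "dbH_kJ_mol": round(bt.dbH, 2),
            "TdbS_kJ_mol": round(bt.TdbS, 2),
            "dbG_kJ_mol": round(bt.dbG, 2),
            "n_ligands": bt.n_ligands,
        }
        for name, bt in items
    ]
    return pd.DataFrame(data)


def format_binding_table(df: pd.DataFrame) -> str:
    """Aligned plain-text rendering of a binding table."""
    return df.to_string(index=False)
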
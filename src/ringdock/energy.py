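"""Single-point energy scoring.

The production scoring path of the protocol is a semi-empirical
quantum-chemical heat of formation obtained through an external engine
(see :mod:`ringdock.engines`).  For desk-scale runs and testing this
module provides a classical *surrogate*: a pairwise 12-6
dispersion–repulsion term with Lorentz–Berthelot combination plus a
dielectric-screened point-charge term, summed over inter-molecular atom
pairs only and truncated at a plain distance cutoff.  Its zero of energy
is arbitrary; only binding differences are meaningful.

All energies are kJ mol⁻¹; adapters convert external units at the
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import ActiveSiteModel, Molecule

__all__ = ["EnergyResult", "SurrogateParams", "score_surrogate",
           "score_surrogate_batch", "binding_energy", "COULOMB_KJ_A"]

# e^2 * N_A / (4 pi eps0), in kJ mol^-1 Å
COULOMB_KJ_A = 1389.35457644382


@dataclass(frozen=True)
class EnergyResult:
    """A scored species: energy in kJ mol⁻¹ (heat of formation for QM
    backends, arbitrary-zero potential for the surrogate)."""

    energy: float
    backend_id: str
    converged: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.energy):
            raise ValueError(f"non-finite energy from backend {self.backend_id!r}")
        if not self.backend_id:
            raise ValueError("backend_id must be non-empty")


# Per-element Lennard-Jones well depths (kJ/mol) and sizes (Å); generic
# organic-forcefield magnitudes.  Default partial charges are zero —
# charged sites are introduced per atom (Atom.charge) or by overriding
# ``charges`` per element.
_DEFAULT_EPSILON = {
    "H": 0.12, "C": 0.29, "N": 0.71, "O": 0.88, "F": 0.61,
    "P": 0.84, "S": 1.05, "CL": 1.10,
}
_DEFAULT_SIGMA = {
    "H": 2.40, "C": 3.40, "N": 3.25, "O": 3.00, "F": 2.95,
    "P": 3.70, "S": 3.55, "CL": 3.45,
}


@dataclass(frozen=True)
class SurrogateParams:
    """Parameters of the classical surrogate scorer."""

    epsilon: dict = field(default_factory=lambda: dict(_DEFAULT_EPSILON))
    sigma: dict = field(default_factory=lambda: dict(_DEFAULT_SIGMA))
    charges: dict = field(default_factory=dict)  # element -> e, default 0
    dielectric: float = 1.0
    cutoff: float = 12.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")
        for name, table in (("epsilon", self.epsilon), ("sigma", self.sigma)):
            for el, v in table.items():
                if v <= 0:
                    raise ValueError(f"{name}[{el!r}] must be positive, got {v}")

    def atom_arrays(self, mol: Molecule | ActiveSiteModel
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-atom (epsilon, sigma, charge) arrays; per-atom charges on
        the structure override the per-element defaults."""
        eps, sig, q = [], [], []
        for a in mol.atoms:
            el = a.element.upper()
            if el not in self.epsilon or el not in self.sigma:
                raise KeyError(
                    f"no surrogate LJ parameters for element {a.element!r} "
                    f"(atom {a.atom_name or '?'})"
                )
            eps.append(self.epsilon[el])
            sig.append(self.sigma[el])
            q.append(a.charge if a.charge is not None else self.charges.get(el, 0.0))
        return np.array(eps), np.array(sig), np.array(q)


def _pair_energy_matrix(ci, ei, si, qi, cj, ej, sj, qj, params) -> float:
    diff = ci[:, None, :] - cj[None, :, :]
    r = np.sqrt(np.einsum("ijx,ijx->ij", diff, diff))
    mask = r <= params.cutoff
    r = np.where(mask & (r > 0), r, np.inf)
    sig = 0.5 * (si[:, None] + sj[None, :])
    eps = np.sqrt(ei[:, None] * ej[None, :])
    x6 = (sig / r) ** 6
    lj = 4.0 * eps * (x6 * x6 - x6)
    coul = COULOMB_KJ_A * qi[:, None] * qj[None, :] / (params.dielectric * r)
    return float(np.sum(lj + coul))


def score_surrogate(
    receptor: ActiveSiteModel | Molecule,
    placed_ligands: list[Molecule],
    params: SurrogateParams = SurrogateParams(),
) -> EnergyResult:
    """Score a placed complex: sum of 12-6 + screened-Coulomb terms over
    all inter-molecular pairs (receptor–ligand and ligand–ligand).

    With no ligands the inter-molecular sum is exactly zero, so the
    surrogate "species energy" of the isolated receptor or of an isolated
    rigid ligand vanishes and the complex score *is* the binding energy.
    """
    groups = [receptor] + list(placed_ligands)
    arrays = [(g.coords, *params.atom_arrays(g)) for g in groups]
    total = 0.0
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            ci, ei, si, qi = arrays[i]
            cj, ej, sj, qj = arrays[j]
            total += _pair_energy_matrix(ci, ei, si, qi, cj, ej, sj, qj, params)
    return EnergyResult(energy=total, backend_id="surrogate")


def score_surrogate_batch(
    receptor_arrays: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    ligand_coords: list[np.ndarray],
    ligand_params: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    params: SurrogateParams = SurrogateParams(),
) -> np.ndarray:
    """Vectorised surrogate scores for a batch of poses.

    Parameters
    ----------
    receptor_arrays : (coords (R,3), eps (R,), sigma (R,), charge (R,)).
    ligand_coords : one (n, A_k, 3) array per ligand copy.
    ligand_params : one (eps, sigma, charge) tuple per ligand copy.

    Returns
    -------
    (n,) total inter-molecular energies, kJ mol⁻¹.
    """
    rc, re, rs, rq = receptor_arrays
    n = ligand_coords[0].shape[0]
    total = np.zeros(n)

    def _accum(ca, pa, cb, pb):
        ea, sa, qa = pa
        eb, sb, qb = pb
        diff = ca[:, :, None, :] - cb[:, None, :, :]
        r = np.sqrt(np.einsum("nabx,nabx->nab", diff, diff))
        mask = r <= params.cutoff
        r = np.where(mask & (r > 0), r, np.inf)
        sig = 0.5 * (sa[None, :, None] + sb[None, None, :])
        eps = np.sqrt(ea[None, :, None] * eb[None, None, :])
        x6 = (sig / r) ** 6
        lj = 4.0 * eps * (x6 * x6 - x6)
        coul = (COULOMB_KJ_A / params.dielectric) * \
            qa[None, :, None] * qb[None, None, :] / r
        return np.sum(lj + coul, axis=(1, 2))

    rc_b = np.broadcast_to(rc, (n,) + rc.shape)
    for lc, lp in zip(ligand_coords, ligand_params):
        total += _accum(lc, lp, rc_b, (re, rs, rq))
    for i in range(len(ligand_coords)):
        for j in range(i + 1, len(ligand_coords)):
            total += _accum(ligand_coords[i], ligand_params[i],
                            ligand_coords[j], ligand_params[j])
    return total


def binding_energy(e_complex: float, e_site: float, e_ligand: float,
                   n_ligands: int = 1) -> float:
    """ΔE_bind = E(complex) − E(site) − n · E(ligand), all kJ mol⁻¹."""
    if n_ligands < 1:
        raise ValueError(f"n_ligands must be >= 1, got {n_ligands}")
    for name, v in (("e_complex", e_complex), ("e_site", e_site),
                    ("e_ligand", e_ligand)):
        if not np.isfinite(v):
            raise ValueError(f"{name} is not finite: {v}")
    return e_complex - e_site - n_ligands * e_ligand
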
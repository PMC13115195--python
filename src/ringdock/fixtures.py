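"""Synthetic structures and engine outputs for download-free runs.

Everything here is generated programmatically and is *synthetic*: a toy
receptor cage with a designed binding well, idealized rigid
three-membered-ring ligands, a residue scaffold for exercising
active-site extraction on realistic residue lists, and engine-output
texts in the adapter's minimal grammar.  None of it attempts to
reproduce a real enzyme pocket; it exists so every stage of the
pipeline can run and be verified at desk scale.

Every generator is a pure function of its arguments (plus an explicit
seed where randomness is involved).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .energy import COULOMB_KJ_A, SurrogateParams
from .structure import ActiveSiteModel, Atom, Molecule

__all__ = ["ToyCageSpec", "make_toy_cage", "make_probe", "make_rigid_ring",
           "make_engine_output", "make_residue_scaffold",
           "grid_search_minimum", "RING_KINDS"]


# ---------------------------------------------------------------------------
# Toy receptor cage with a designed binding well
# ---------------------------------------------------------------------------

PROBE_CHARGE = 0.4  # e, on the single-carbon probe ligand


@dataclass(frozen=True)
class ToyCageSpec:
    """A spherical shell of frozen carbon atoms enclosing a three-oxygen
    binding pocket whose surrogate-energy global minimum for the probe
    ligand sits at ``well_position`` (verified by grid search at build
    time)."""

    n_shell_atoms: int = 30
    radius: float = 8.0
    well_position: tuple[float, float, float] = (1.5, -1.0, 0.8)
    well_depth: float = 60.0  # kJ/mol, approximate depth of the pocket
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("cage radius must be positive")
        if np.linalg.norm(self.well_position) >= self.radius - 1.0:
            raise ValueError("well must lie well inside the cage")
        if self.well_depth <= 0:
            raise ValueError("well depth must be positive")


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return radius * np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _pair_potential(r: float, q_attractor: float,
                    params: SurrogateParams) -> float:
    """Probe(C, +PROBE_CHARGE) vs attractor(O, q) pair energy."""
    eps = np.sqrt(params.epsilon["C"] * params.epsilon["O"])
    sig = 0.5 * (params.sigma["C"] + params.sigma["O"])
    x6 = (sig / r) ** 6
    return 4.0 * eps * (x6 * x6 - x6) + \
        COULOMB_KJ_A * PROBE_CHARGE * q_attractor / (params.dielectric * r)


def _design_pocket(well_depth: float, params: SurrogateParams
                   ) -> tuple[float, float]:
    """Choose the attractor charge and equilibrium distance so that three
    equidistant attractors give a pocket of roughly ``well_depth``."""
    target = -well_depth / 3.0

    def depth_at(q: float) -> float:
        res = minimize_scalar(lambda r: _pair_potential(r, -q, params),
                              bounds=(2.0, 8.0), method="bounded")
        return float(res.fun)

    q = brentq(lambda q: depth_at(q) - target, 1e-4, 2.0, xtol=1e-6)
    r_eq = minimize_scalar(lambda r: _pair_potential(r, -q, params),
                           bounds=(2.0, 8.0), method="bounded").x
    return float(q), float(r_eq)


def make_toy_cage(spec: ToyCageSpec = ToyCageSpec(), *,
                  verify: bool = True,
                  params: SurrogateParams = SurrogateParams()
                  ) -> ActiveSiteModel:
    """Build the toy receptor: shell + three-oxygen pocket + floor plug.

    The pocket is an equilateral triangle of negatively charged oxygens
    below ``well_position`` plus a neutral carbon plug that blocks the
    mirror-image site, making the well a unique point.  With
    ``verify=True`` a grid search re-locates the global minimum and an
    error is raised if it strays more than 0.5 Å from the requested
    position.
    """
    rng = np.random.default_rng(spec.seed)
    shell = _fibonacci_sphere(spec.n_shell_atoms, spec.radius)
    shell += rng.normal(scale=0.05, size=shell.shape)
    # renormalise so every shell atom sits exactly on the sphere
    shell *= spec.radius / np.linalg.norm(shell, axis=1)[:, None]

    well = np.asarray(spec.well_position, dtype=float)
    axis = -well / np.linalg.norm(well) if np.linalg.norm(well) > 1e-9 \
        else np.array([0.0, 0.0, -1.0])
    # axis points from the well toward the cage centre; the attractor
    # triangle sits between the well and the centre, the plug beyond it
    q_att, r_eq = _design_pocket(spec.well_depth, params)
    rho = 1.75  # triangle circumradius, Å
    h = float(np.sqrt(max(r_eq**2 - rho**2, 1.0)))
    plane_center = well + h * axis

    # orthonormal frame in the triangle plane
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)

    atoms: list[Atom] = []
    for i, pos in enumerate(shell):
        atoms.append(Atom(element="C", coords=pos, residue_name="CAG",
                          residue_number=1, atom_name=f"C{i+1}",
                          frozen=True, charge=0.0))
    for k in range(3):
        ang = 2.0 * np.pi * k / 3.0
        pos = plane_center + rho * (np.cos(ang) * u + np.sin(ang) * v)
        atoms.append(Atom(element="O", coords=pos, residue_name="WEL",
                          residue_number=2, atom_name=f"O{k+1}",
                          frozen=True, charge=-q_att))
    plug = plane_center + 1.2 * axis
    atoms.append(Atom(element="C", coords=plug, residue_name="WEL",
                      residue_number=2, atom_name="CPL",
                      frozen=True, charge=0.0))

    n_shell = spec.n_shell_atoms
    model = ActiveSiteModel(
        atoms=atoms,
        residue_index={1: list(range(n_shell)),
                       2: list(range(n_shell, n_shell + 4))},
        source_id=f"toy-cage(seed={spec.seed})",
    )
    if verify:
        pos, _ = grid_search_minimum(model, params=params, spacing=0.5)
        pos, _ = grid_search_minimum(model, params=params, spacing=0.1,
                                     bounds=(pos - 0.75, pos + 0.75))
        if np.linalg.norm(pos - well) > 0.5:
            raise RuntimeError(
                f"toy cage self-check failed: grid minimum {pos} is "
                f"{np.linalg.norm(pos - well):.2f} Å from requested well"
            )
    return model


def make_probe(charge: float = PROBE_CHARGE) -> Molecule:
    """The single-carbon probe ligand used with the toy cage."""
    return Molecule(
        atoms=[Atom(element="C", coords=np.zeros(3), atom_name="C1",
                    charge=charge)],
        name="probe", rigid=True,
    )


def grid_search_minimum(receptor: ActiveSiteModel,
                        params: SurrogateParams = SurrogateParams(),
                        spacing: float = 0.25,
                        bounds: tuple[np.ndarray, np.ndarray] | None = None,
                        probe_charge: float = PROBE_CHARGE
                        ) -> tuple[np.ndarray, float]:
    """Dense-grid oracle: surrogate energy of the single-atom probe on a
    regular grid; returns (position, energy) of the grid minimum."""
    coords = receptor.coords
    eps_r, sig_r, q_r = params.atom_arrays(receptor)
    eps_p = np.sqrt(params.epsilon["C"] * eps_r)
    sig_p = 0.5 * (params.sigma["C"] + sig_r)
    if bounds is None:
        lo = coords.min(axis=0) + 2.0
        hi = coords.max(axis=0) - 2.0
    else:
        lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    axes = [np.arange(lo[d], hi[d] + spacing / 2, spacing) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    best_e, best_p = np.inf, grid[0]
    for chunk in np.array_split(grid, max(1, len(grid) // 20000)):
        diff = chunk[:, None, :] - coords[None, :, :]
        r = np.sqrt(np.einsum("gax,gax->ga", diff, diff))
        r = np.where((r <= params.cutoff) & (r > 0), r, np.inf)
        x6 = (sig_p[None, :] / r) ** 6
        e = np.sum(4.0 * eps_p[None, :] * (x6 * x6 - x6)
                   + COULOMB_KJ_A * probe_charge * q_r[None, :]
                   / (params.dielectric * r), axis=1)
        i = int(np.argmin(e))
        if e[i] < best_e:
            best_e, best_p = float(e[i]), chunk[i]
    return np.asarray(best_p, float), best_e


# ---------------------------------------------------------------------------
# Idealized rigid three-membered rings
# ---------------------------------------------------------------------------

RING_KINDS = ("cyclopropane", "aziridine", "oxirane", "phosphirane",
              "thiirane")

# idealized textbook bond lengths, Å
_RING_GEOM = {
    # kind: (hetero element or None, C-C, C-X, X-H or None)
    "cyclopropane": (None, 1.510, 1.510, None),
    "aziridine": ("N", 1.481, 1.475, 1.016),
    "oxirane": ("O", 1.466, 1.436, None),
    "phosphirane": ("P", 1.502, 1.867, 1.421),
    "thiirane": ("S", 1.484, 1.815, None),
}
_CH = 1.083
_HCH_DEG = 115.0


def _ch2_hydrogens(c: np.ndarray, u_out: np.ndarray, normal: np.ndarray
                   ) -> list[np.ndarray]:
    """Two C–H vectors in the (u_out, normal) plane, symmetric about
    u_out with the idealized H–C–H angle."""
    gamma = np.deg2rad(_HCH_DEG / 2.0)
    return [c + _CH * (np.cos(gamma) * u_out + s * np.sin(gamma) * normal)
            for s in (+1.0, -1.0)]


def make_rigid_ring(kind: str) -> Molecule:
    """Idealized geometry of a three-membered ring with explicit
    hydrogens, centred at the origin, ring in the xy-plane; rigid."""
    if kind not in _RING_GEOM:
        raise ValueError(
            f"unknown ring kind {kind!r}; choose from {RING_KINDS}"
        )
    hetero, b_cc, b_cx, b_xh = _RING_GEOM[kind]
    normal = np.array([0.0, 0.0, 1.0])
    if hetero is None:
        rc = b_cc / np.sqrt(3.0)
        ring = [("C", rc * np.array([np.cos(a), np.sin(a), 0.0]))
                for a in (np.pi / 2, np.pi / 2 + 2 * np.pi / 3,
                          np.pi / 2 + 4 * np.pi / 3)]
    else:
        y_x = float(np.sqrt(b_cx**2 - (b_cc / 2.0) ** 2))
        ring = [(hetero, np.array([0.0, y_x, 0.0])),
                ("C", np.array([-b_cc / 2.0, 0.0, 0.0])),
                ("C", np.array([+b_cc / 2.0, 0.0, 0.0]))]
    centroid = np.mean([p for _, p in ring], axis=0)
    ring = [(el, p - centroid) for el, p in ring]

    atoms = [Atom(element=el, coords=p, atom_name=f"{el}{i+1}")
             for i, (el, p) in enumerate(ring)]
    for el, p in ring:
        if el == "C":
            u_out = p / np.linalg.norm(p)
            for h in _ch2_hydrogens(p, u_out, normal):
                atoms.append(Atom(element="H", coords=h,
                                  atom_name=f"H{len(atoms)+1}"))
        elif b_xh is not None:
            # pyramidal X–H pointing out of the ring plane
            u_out = p / np.linalg.norm(p)
            direction = np.cos(np.deg2rad(60)) * u_out \
                + np.sin(np.deg2rad(60)) * normal
            atoms.append(Atom(element="H", coords=p + b_xh * direction,
                              atom_name=f"H{len(atoms)+1}",
                              is_polar_hydrogen=(el in ("N", "O"))))
    return Molecule(atoms=atoms, name=kind, rigid=True)


# ---------------------------------------------------------------------------
# Synthetic engine output (adapter grammar)
# ---------------------------------------------------------------------------

def make_engine_output(species_id: str, dHf: float, TdS: float | None = None,
                       converged: bool = True) -> str:
    """Engine-output text in the MOPAC-style minimal grammar, carrying a
    heat of formation and, when ``TdS`` is given, a thermochemistry
    block with ΔfG° = ΔfH° − T·ΔfS°."""
    if not np.isfinite(dHf):
        raise ValueError("dHf must be finite")
    lines = [
        " *** synthetic engine output (MOPAC-style grammar) ***",
        f" SPECIES: {species_id}",
        "",
        f" FINAL HEAT OF FORMATION = {dHf:.5f} KJ/MOL",
    ]
    if TdS is not None:
        if not np.isfinite(TdS):
            raise ValueError("TdS must be finite")
        dGf = dHf - TdS
        lines += [
            "",
            " THERMOCHEMISTRY AT T = 298.15 K, P = 101325 PA",
            f" ENTHALPY OF FORMATION = {dHf:.5f} KJ/MOL",
            f" T.DELTA-S CONTRIBUTION = {TdS:.5f} KJ/MOL",
            f" GIBBS ENERGY OF FORMATION = {dGf:.5f} KJ/MOL",
        ]
    if converged:
        lines += ["", " * JOB ENDED NORMALLY *"]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Synthetic residue scaffold (for active-site extraction)
# ---------------------------------------------------------------------------

_BACKBONE_OFFSETS = {
    "N": np.array([0.0, 0.0, 0.0]),
    "CA": np.array([1.46, 0.0, 0.0]),
    "C": np.array([2.0, 1.4, 0.0]),
    "O": np.array([1.6, 2.5, 0.2]),
}


def make_residue_scaffold(residues, *, rise: float = 1.6,
                          turn_deg: float = 100.0,
                          helix_radius: float = 9.0) -> Molecule:
    """A synthetic single-chain backbone trace carrying the requested
    ``(residue_name, residue_number)`` annotations.

    Residues are laid out along a coarse helix — geometry is arbitrary
    but clash-free; only the residue bookkeeping is meaningful.
    """
    atoms: list[Atom] = []
    for i, (name, number) in enumerate(residues):
        ang = np.deg2rad(turn_deg * i)
        base = np.array([helix_radius * np.cos(ang),
                         helix_radius * np.sin(ang),
                         rise * i])
        for atom_name, off in _BACKBONE_OFFSETS.items():
            atoms.append(Atom(
                element=atom_name[0],
                coords=base + off,
                residue_name=name.strip().upper(),
                residue_number=int(number),
                atom_name=atom_name,
            ))
    return Molecule(atoms=atoms, name="synthetic-scaffold")
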
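"""Binary steric-overlap filter.

A placed pose is discarded when any inter-molecular atom pair — ligand
vs. receptor or ligand vs. ligand — sits closer than
``scale * (r_vdw_i + r_vdw_j)``.  Intra-molecular pairs are never
checked (ligands are rigid; the receptor is frozen).  The default scale
of 0.7 on summed van der Waals radii is the common steric-clash
convention; the filter is binary, with no soft-core grading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .data.radii import RADII_SETS, vdw_radius
from .structure import ActiveSiteModel, Molecule

__all__ = ["ClashCriterion", "NeighborGrid", "build_neighbor_grid",
           "has_clash", "clash_mask_batch"]


@dataclass(frozen=True)
class ClashCriterion:
    """Overlap rule: distance < scale · (r_i + r_j) on vdW radii."""

    scale: float = 0.7
    radii_set: str = "bondi"
    include_hydrogens: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.scale <= 1.0):
            raise ValueError(f"clash scale must be in (0, 1], got {self.scale}")
        if self.radii_set not in RADII_SETS:
            raise ValueError(f"unknown radii set {self.radii_set!r}")

    def radii_for(self, elements: list[str]) -> np.ndarray:
        return np.array([vdw_radius(e, self.radii_set) for e in elements])


class NeighborGrid:
    """Spatial index over a fixed atom set.

    Backed by a k-d tree; ``cell`` is the guaranteed query radius —
    ``query(point)`` returns a superset of every atom within ``cell`` of
    the probe (in fact exactly those atoms), never a false negative.
    """

    def __init__(self, coords: np.ndarray, cell: float):
        if cell <= 0:
            raise ValueError(f"cell size must be positive, got {cell}")
        self.cell = float(cell)
        self.coords = np.atleast_2d(np.asarray(coords, dtype=float))
        self._tree = cKDTree(self.coords)

    def query(self, point: np.ndarray, radius: float | None = None) -> list[int]:
        """Indices of atoms within ``radius`` (default: the cell size)."""
        r = self.cell if radius is None else radius
        if r > self.cell:
            raise ValueError(
                f"query radius {r} exceeds guaranteed cell radius {self.cell}"
            )
        return sorted(self._tree.query_ball_point(np.asarray(point, float), r))


def build_neighbor_grid(atoms, cell: float) -> NeighborGrid:
    """Index a list of atoms (or an ``(n, 3)`` array) for radius queries."""
    if hasattr(atoms, "shape") or (atoms and hasattr(atoms[0], "shape")):
        coords = np.asarray(atoms, dtype=float)
    else:
        coords = np.array([a.coords for a in atoms], dtype=float)
    return NeighborGrid(coords, cell)


def _filtered(mol, criterion: ClashCriterion) -> tuple[np.ndarray, np.ndarray]:
    elements = mol.elements
    coords = mol.coords
    radii = criterion.radii_for(elements)
    if not criterion.include_hydrogens:
        keep = np.array([e.upper() != "H" for e in elements])
        coords, radii = coords[keep], radii[keep]
    return coords, radii


def has_clash(
    receptor: ActiveSiteModel | Molecule,
    placed_ligands: list[Molecule],
    criterion: ClashCriterion = ClashCriterion(),
) -> tuple[bool, tuple[int, int, int, int] | None]:
    """Check one placed complex for steric overlap.

    Returns ``(clash, pair)`` where ``pair`` identifies the first
    offending atom pair found as ``(mol_i, atom_i, mol_j, atom_j)`` with
    molecule index 0 = receptor and 1.. = ligands in order, or ``None``.
    The verdict is symmetric in ligand order; "first" follows molecule
    then atom index order for determinism.
    """
    groups = [_filtered(receptor, criterion)] + [
        _filtered(lig, criterion) for lig in placed_ligands
    ]
    max_r = max((r.max() for _, r in groups if len(r)), default=0.0)
    reach = 2.0 * max_r * criterion.scale
    trees = [cKDTree(c) for c, _ in groups]
    for i in range(len(groups)):
        ci, ri = groups[i]
        for j in range(i + 1, len(groups)):
            cj, rj = groups[j]
            pairs = trees[i].query_ball_tree(trees[j], reach)
            best: tuple[int, int] | None = None
            for ai in range(len(ci)):
                for aj in pairs[ai]:
                    cutoff = criterion.scale * (ri[ai] + rj[aj])
                    d = np.linalg.norm(ci[ai] - cj[aj])
                    if d < cutoff:
                        cand = (ai, aj)
                        if best is None or cand < best:
                            best = cand
            if best is not None:
                return True, (i, best[0], j, best[1])
    return False, None


def clash_mask_batch(
    receptor_coords: np.ndarray,
    receptor_radii: np.ndarray,
    ligand_coords: list[np.ndarray],
    ligand_radii: list[np.ndarray],
    scale: float,
) -> np.ndarray:
    """Vectorised clash verdicts for a batch of placed poses.

    Parameters
    ----------
    receptor_coords, receptor_radii : (R, 3) and (R,) receptor arrays.
    ligand_coords : one (n, A_k, 3) array per ligand copy (same n).
    ligand_radii : one (A_k,) radii array per ligand copy.
    scale : clash scale on summed vdW radii.

    Returns
    -------
    (n,) boolean array, True where the pose has any inter-molecular
    overlap (ligand–receptor or ligand–ligand).
    """
    n = ligand_coords[0].shape[0]
    clash = np.zeros(n, dtype=bool)
    for lc, lr in zip(ligand_coords, ligand_radii):
        # (n, A, R) distances ligand vs receptor
        diff = lc[:, :, None, :] - receptor_coords[None, None, :, :]
        d2 = np.einsum("narx,narx->nar", diff, diff)
        cut = scale * (lr[None, :, None] + receptor_radii[None, None, :])
        clash |= np.any(d2 < cut * cut, axis=(1, 2))
    for i in range(len(ligand_coords)):
        for j in range(i + 1, len(ligand_coords)):
            diff = ligand_coords[i][:, :, None, :] - ligand_coords[j][:, None, :, :]
            d2 = np.einsum("nabx,nabx->nab", diff, diff)
            cut = scale * (ligand_radii[i][None, :, None]
                           + ligand_radii[j][None, None, :])
            clash |= np.any(d2 < cut * cut, axis=(1, 2))
    return clash
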
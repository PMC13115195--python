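"""Rigid-body pose generation: uniform random rotations and translations.

A pose is a translation plus a unit quaternion; rotations act about the
ligand centroid so translation and rotation sampling are independent.
The proposal stream is a pure function of ``(seed, config)``: the random
generator is numpy's PCG64 and the draw order is fixed as (translation
x, y, z, then quaternion u1, u2, u3) per ligand, ligands in index order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import ActiveSiteModel, Molecule

__all__ = [
    "Pose",
    "MultiPose",
    "SamplingRegion",
    "random_rotation",
    "propose_multipose",
    "propose_batch",
    "apply_pose",
    "apply_pose_batch",
    "compose_poses",
    "region_from_model",
    "rotation_angle",
]


@dataclass(frozen=True)
class Pose:
    """A rigid transform: rotate about the ligand centroid by ``rotation``
    (unit quaternion, scalar-first ``(w, x, y, z)``), then translate."""

    translation: tuple[float, float, float]
    rotation: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        q = np.asarray(self.rotation, dtype=float)
        norm = float(np.linalg.norm(q))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"quaternion norm {norm} != 1")

    @staticmethod
    def identity() -> "Pose":
        return Pose((0.0, 0.0, 0.0), (1.0, 0.0, 0.0, 0.0))


@dataclass(frozen=True)
class MultiPose:
    """One pose per ligand copy, in ligand index order."""

    poses: tuple[Pose, ...]

    def __len__(self) -> int:
        return len(self.poses)


@dataclass(frozen=True)
class SamplingRegion:
    """Axis-aligned box or sphere from which ligand centroids are drawn."""

    center: tuple[float, float, float]
    shape: str = "box"  # "box" | "sphere"
    half_extents: tuple[float, float, float] | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        if self.shape == "box":
            if self.half_extents is None or any(h <= 0 for h in self.half_extents):
                raise ValueError("box region needs strictly positive half_extents")
        elif self.shape == "sphere":
            if self.radius is None or self.radius <= 0:
                raise ValueError("sphere region needs a strictly positive radius")
        else:
            raise ValueError(f"unknown region shape {self.shape!r}")

    def contains(self, points: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(self.center)
        if self.shape == "box":
            he = np.asarray(self.half_extents)
            return np.all(np.abs(pts) <= he + atol, axis=-1)
        return np.linalg.norm(pts, axis=-1) <= self.radius + atol

    def sample_translations(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` centroid positions, consuming exactly 3 uniforms each."""
        u = rng.random((n, 3))
        c = np.asarray(self.center, dtype=float)
        if self.shape == "box":
            he = np.asarray(self.half_extents, dtype=float)
            return c + (2.0 * u - 1.0) * he
        # sphere point picking: direction from (u1, u2), radius from u3
        cos_t = 1.0 - 2.0 * u[:, 0]
        sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
        phi = 2.0 * np.pi * u[:, 1]
        r = self.radius * np.cbrt(u[:, 2])
        return c + (r * np.stack(
            [sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1).T).T


def region_from_model(model: ActiveSiteModel | Molecule, pad: float = -2.0,
                      min_half_extent: float = 0.5) -> SamplingRegion:
    """Default sampling region: the axis-aligned bounding box of the
    receptor atoms, padded by ``pad`` Å per side (negative = shrunk, which
    keeps sampled centroids interior to the model)."""
    coords = model.coords
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    center = (lo + hi) / 2.0
    half = np.maximum((hi - lo) / 2.0 + pad, min_half_extent)
    return SamplingRegion(center=tuple(center), shape="box",
                          half_extents=tuple(half))


def _quat_from_uniforms(u: np.ndarray) -> np.ndarray:
    """Shoemake's subgroup algorithm: map (n, 3) uniforms on [0,1) to
    quaternions uniform on SO(3), scalar-first."""
    u1, u2, u3 = u[:, 0], u[:, 1], u[:, 2]
    a, b = np.sqrt(1.0 - u1), np.sqrt(u1)
    t2, t3 = 2.0 * np.pi * u2, 2.0 * np.pi * u3
    # (w, x, y, z)
    q = np.stack([b * np.cos(t3), a * np.sin(t2), a * np.cos(t2), b * np.sin(t3)],
                 axis=1)
    return q


def random_rotation(rng: np.random.Generator) -> tuple[float, float, float, float]:
    """One rotation uniform on SO(3), as a scalar-first unit quaternion.

    Consumes exactly three uniform draws.
    """
    q = _quat_from_uniforms(rng.random((1, 3)))[0]
    return tuple(float(v) for v in q)


def rotation_angle(quaternion: Iterable[float]) -> float:
    """Rotation angle in [0, π] encoded by a scalar-first unit quaternion."""
    q = np.asarray(tuple(quaternion), dtype=float)
    return 2.0 * float(np.arccos(np.clip(abs(q[0]), 0.0, 1.0)))


def propose_multipose(region: SamplingRegion, n_ligands: int,
                      rng: np.random.Generator) -> MultiPose:
    """Draw one multi-ligand proposal: independent uniform pose per copy."""
    if n_ligands < 1:
        raise ValueError(f"n_ligands must be >= 1, got {n_ligands}")
    poses = []
    for _ in range(n_ligands):
        t = region.sample_translations(1, rng)[0]
        q = random_rotation(rng)
        poses.append(Pose(tuple(float(v) for v in t), q))
    return MultiPose(tuple(poses))


def propose_batch(region: SamplingRegion, n_ligands: int, n: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised proposal stream: ``n`` multi-poses at once.

    Returns ``(translations, quaternions)`` with shapes (n, n_ligands, 3)
    and (n, n_ligands, 4).  Draw order is identical to calling
    :func:`propose_multipose` ``n`` times, so streamed and batched runs
    with the same seed produce the same poses.
    """
    if n_ligands < 1:
        raise ValueError(f"n_ligands must be >= 1, got {n_ligands}")
    # one (n_ligands * 2) x 3 uniform block per proposal, in draw order
    u = rng.random((n, n_ligands, 2, 3))
    trans = np.empty((n, n_ligands, 3))
    quats = np.empty((n, n_ligands, 4))
    for j in range(n_ligands):
        region_u = u[:, j, 0, :]
        c = np.asarray(region.center, dtype=float)
        if region.shape == "box":
            he = np.asarray(region.half_extents, dtype=float)
            trans[:, j, :] = c + (2.0 * region_u - 1.0) * he
        else:
            cos_t = 1.0 - 2.0 * region_u[:, 0]
            sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
            phi = 2.0 * np.pi * region_u[:, 1]
            r = region.radius * np.cbrt(region_u[:, 2])
            trans[:, j, :] = c + np.stack(
                [r * sin_t * np.cos(phi), r * sin_t * np.sin(phi), r * cos_t],
                axis=1)
        quats[:, j, :] = _quat_from_uniforms(u[:, j, 1, :])
    return trans, quats


def _rotation_from_quat(q: np.ndarray) -> Rotation:
    q = np.asarray(q, dtype=float)
    # scipy expects scalar-last
    return Rotation.from_quat(np.concatenate([q[..., 1:], q[..., :1]], axis=-1))


def apply_pose(ligand: Molecule, pose: Pose) -> Molecule:
    """Rotate ``ligand`` about its centroid, then translate its centroid to
    ``pose.translation``.  The input molecule is left unmodified."""
    if not ligand.rigid:
        raise ValueError(f"ligand {ligand.name!r} is not marked rigid")
    coords = ligand.coords
    centroid = coords.mean(axis=0)
    rot = _rotation_from_quat(np.asarray(pose.rotation))
    new = rot.apply(coords - centroid) + np.asarray(pose.translation)
    return ligand.with_coords(new)


def apply_pose_batch(coords: np.ndarray, translations: np.ndarray,
                     quaternions: np.ndarray) -> np.ndarray:
    """Apply ``n`` poses to one ligand coordinate set.

    Parameters
    ----------
    coords : (A, 3) ligand coordinates.
    translations : (n, 3) centroid target positions.
    quaternions : (n, 4) scalar-first unit quaternions.

    Returns
    -------
    (n, A, 3) transformed coordinates.
    """
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    mats = _rotation_from_quat(np.asarray(quaternions)).as_matrix()  # (n, 3, 3)
    return np.einsum("nij,aj->nai", mats, centered) + translations[:, None, :]


def compose_poses(second: Pose, first: Pose) -> Pose:
    """The single pose equivalent to applying ``first`` then ``second``.

    With centroid-centred rotations the translations add and the
    quaternions multiply: applying ``first`` moves the centroid to its
    translation, and ``second`` then rotates about that new centroid.
    Here poses store absolute centroid targets, so the composed
    translation is simply ``second.translation``.
    """
    q1 = np.asarray(first.rotation)
    q2 = np.asarray(second.rotation)
    w1, v1 = q1[0], q1[1:]
    w2, v2 = q2[0], q2[1:]
    w = w2 * w1 - np.dot(v2, v1)
    v = w2 * v1 + w1 * v2 + np.cross(v2, v1)
    q = np.concatenate([[w], v])
    q = q / np.linalg.norm(q)
    return Pose(second.translation, tuple(float(x) for x in q))
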
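import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ringdock.fixtures import make_rigid_ring
from ringdock.sampling import (MultiPose, Pose, SamplingRegion, apply_pose,
                               apply_pose_batch, compose_poses,
                               propose_batch, propose_multipose,
                               random_rotation, region_from_model,
                               rotation_angle)


def _angle_cdf(theta):
    """CDF of the rotation angle of a uniform rotation: density (1-cos θ)/π."""
    return (np.asarray(theta) - np.sin(theta)) / np.pi


class TestRandomRotation:
    def test_identity_quaternion_fixes_points(self):
        ring = make_rigid_ring("oxirane")
        out = apply_pose(ring, Pose(tuple(ring.centroid), (1, 0, 0, 0)))
        np.testing.assert_allclose(out.coords, ring.coords, atol=1e-12)

    def test_unit_norm(self, rng):
        qs = np.array([random_rotation(rng) for _ in range(500)])
        np.testing.assert_allclose(np.linalg.norm(qs, axis=1), 1.0, atol=1e-9)

    def test_angle_distribution_uniform_so3(self):
        rng = np.random.default_rng(2024)
        qs = np.array([random_rotation(rng) for _ in range(100_000)])
        angles = 2.0 * np.arccos(np.clip(np.abs(qs[:, 0]), 0, 1))
        res = stats.kstest(angles, _angle_cdf)
        assert res.pvalue > 0.01

    def test_axis_isotropy(self):
        rng = np.random.default_rng(7)
        qs = np.array([random_rotation(rng) for _ in range(100_000)])
        axes = qs[:, 1:] / np.linalg.norm(qs[:, 1:], axis=1)[:, None]
        # random sign per sample to remove the q/-q convention, then the
        # mean resultant length of the axis vectors must be ~0
        assert np.linalg.norm(axes.mean(axis=0)) < 0.01


class TestProposals:
    def test_box_containment_and_moments(self):
        rng = np.random.default_rng(3)
        region = SamplingRegion(center=(0, 0, 0), shape="box",
                                half_extents=(1.0, 1.0, 1.0))
        t = region.sample_translations(10_000, rng)
        assert region.contains(t).all()
        se = 2.0 / np.sqrt(12.0) / np.sqrt(len(t))  # std of U(-1,1) / sqrt(n)
        assert np.all(np.abs(t.mean(axis=0)) < 3 * se)

    def test_sphere_containment(self, rng):
        region = SamplingRegion(center=(1, 2, 3), shape="sphere", radius=2.5)
        t = region.sample_translations(5000, rng)
        assert region.contains(t).all()

    def test_multipose_length(self, rng):
        region = SamplingRegion(center=(0, 0, 0), half_extents=(1, 1, 1))
        mp = propose_multipose(region, 2, rng)
        assert isinstance(mp, MultiPose)
        assert len(mp) == 2

    def test_invalid_ligand_count(self, rng):
        region = SamplingRegion(center=(0, 0, 0), half_extents=(1, 1, 1))
        with pytest.raises(ValueError):
            propose_multipose(region, 0, rng)

    def test_seed_reproducibility(self):
        region = SamplingRegion(center=(0, 0, 0), half_extents=(2, 3, 4))
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            runs.append([propose_multipose(region, 2, rng) for _ in range(50)])
        assert runs[0] == runs[1]

    def test_batch_matches_streamed_draw_order(self):
        region = SamplingRegion(center=(0, 0, 0), half_extents=(2, 2, 2))
        rng1 = np.random.default_rng(5)
        trans, quats = propose_batch(region, 2, 20, rng1)
        rng2 = np.random.default_rng(5)
        for i in range(20):
            mp = propose_multipose(region, 2, rng2)
            for j, pose in enumerate(mp.poses):
                np.testing.assert_allclose(pose.translation, trans[i, j],
                                           atol=1e-12)
                np.testing.assert_allclose(pose.rotation, quats[i, j],
                                           atol=1e-12)

    def test_region_from_model_shrinks_bounds(self, cage):
        region = region_from_model(cage)
        coords = cage.coords
        he = np.asarray(region.half_extents)
        np.testing.assert_allclose(
            he, (coords.max(0) - coords.min(0)) / 2 - 2.0, atol=1e-9)


class TestApplyPose:
    def test_half_turn_about_z(self):
        from ringdock.structure import Atom, Molecule
        mol = Molecule(
            atoms=[Atom(element="C", coords=[1, 0, 0]),
                   Atom(element="C", coords=[-1, 0, 0])],
            rigid=True,
        )
        # 180° about z, centroid at origin
        out = apply_pose(mol, Pose((0, 0, 0), (0, 0, 0, 1)))
        np.testing.assert_allclose(out.coords[0], [-1, 0, 0], atol=1e-12)

    def test_input_unmodified(self, rng):
        ring = make_rigid_ring("thiirane")
        before = ring.coords
        apply_pose(ring, Pose((5, 5, 5), random_rotation(rng)))
        np.testing.assert_array_equal(ring.coords, before)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_rigid_distances_preserved(self, seed):
        rng = np.random.default_rng(seed)
        ring = make_rigid_ring("phosphirane")
        pose = Pose(tuple(rng.uniform(-10, 10, 3)), random_rotation(rng))
        out = apply_pose(ring, pose)
        d0 = np.linalg.norm(ring.coords[:, None] - ring.coords[None], axis=-1)
        d1 = np.linalg.norm(out.coords[:, None] - out.coords[None], axis=-1)
        np.testing.assert_allclose(d1, d0, atol=1e-9)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_pose_composition(self, seed):
        rng = np.random.default_rng(seed)
        ring = make_rigid_ring("aziridine")
        p1 = Pose(tuple(rng.uniform(-5, 5, 3)), random_rotation(rng))
        p2 = Pose(tuple(rng.uniform(-5, 5, 3)), random_rotation(rng))
        sequential = apply_pose(apply_pose(ring, p1), p2)
        composed = apply_pose(ring, compose_poses(p2, p1))
        np.testing.assert_allclose(sequential.coords, composed.coords,
                                   atol=1e-9)

    def test_batch_matches_single(self, rng):
        ring = make_rigid_ring("cyclopropane")
        poses = [Pose(tuple(rng.uniform(-8, 8, 3)), random_rotation(rng))
                 for _ in range(25)]
        batch = apply_pose_batch(
            ring.coords,
            np.array([p.translation for p in poses]),
            np.array([p.rotation for p in poses]),
        )
        for i, p in enumerate(poses):
            np.testing.assert_allclose(batch[i], apply_pose(ring, p).coords,
                                       atol=1e-10)

    def test_centroid_lands_on_translation(self, rng):
        ring = make_rigid_ring("oxirane")
        target = (3.0, -2.0, 1.0)
        out = apply_pose(ring, Pose(target, random_rotation(rng)))
        np.testing.assert_allclose(out.centroid, target, atol=1e-9)


class TestPoseValidation:
    def test_non_unit_quaternion_rejected(self):
        with pytest.raises(ValueError, match="norm"):
            Pose((0, 0, 0), (1.0, 0.5, 0, 0))

    def test_rotation_angle(self):
        assert rotation_angle((1, 0, 0, 0)) == pytest.approx(0.0)
        assert rotation_angle((0, 0, 0, 1)) == pytest.approx(np.pi)
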
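import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from smlmfuse.evaluation import (
    angular_shift,
    fsc_resolution,
    moment_align,
    registration_error,
    ring_distance,
    ring_radii,
    success_threshold_check,
    tilt_distribution,
)
from smlmfuse.lie_averaging import AbsolutePoseSet
from smlmfuse.particle_store import LocalizationCloud, RigidTransform, apply_transform
from smlmfuse.simulator import make_npc_model
from tests.conftest import random_rigid_transform


def dense_npc_cloud(model, per_site=50, noise=0.0, rng=None):
    """Localizations exactly at (or jittered about) the NPC sites."""
    pts = np.repeat(model.sites, per_site, axis=0)
    if noise > 0:
        pts = pts + rng.normal(0, noise, pts.shape)
    return LocalizationCloud(pts, sigma_lat=3.0, sigma_ax=9.0)


class TestRegistrationError:
    def test_identical_sets_zero(self, rng):
        sets = np.tile(rng.normal(0, 30, (1, 16, 3)), (4, 1, 1))
        assert registration_error(sets, mode="cyclic") == 0.0

    def test_pure_translation_exact(self, rng):
        base = rng.normal(0, 30, (16, 3))
        sets = np.stack([base, base + [5.0, 0, 0]])
        assert np.isclose(registration_error(sets, mode="none"), 5.0, atol=1e-12)

    def test_cyclic_shift_absorbed(self, rng):
        base = rng.normal(0, 30, (16, 3))
        shifted = np.roll(base, 3, axis=0)
        sets = np.stack([base, shifted])
        assert registration_error(sets, mode="cyclic") < 1e-12
        # brute-force scan over all K shifts agrees
        brute = min(np.sqrt(np.mean(np.sum(
            (base - np.roll(shifted, -k, axis=0)) ** 2, axis=1)))
            for k in range(16))
        assert np.isclose(registration_error(sets, mode="cyclic"), brute)

    def test_global_rigid_transform_invariance(self, rng):
        sets = rng.normal(0, 30, (5, 12, 3))
        T = random_rigid_transform(rng)
        moved = np.stack([T.apply(s) for s in sets])
        assert np.isclose(registration_error(sets, mode="cyclic"),
                          registration_error(moved, mode="cyclic"), rtol=1e-9)

    def test_symmetric_in_pair_order(self, rng):
        sets = rng.normal(0, 30, (3, 8, 3))
        rev = sets[::-1]
        assert np.isclose(registration_error(sets, "cyclic"),
                          registration_error(rev, "cyclic"), rtol=1e-12)

    def test_per_ring_shift_absorbs_c8_rotation(self, npc_model):
        g = Rotation.from_rotvec([0, 0, np.pi / 4]).as_matrix()
        sets = np.stack([npc_model.sites, npc_model.sites @ g.T])
        err = registration_error(sets, mode="cyclic", ring_size=16)
        assert err < 1e-9


class TestSuccessThreshold:
    @pytest.mark.parametrize("error,ok", [(10.0, True), (24.9, True),
                                          (25.0, False), (30.0, False)])
    def test_boundary(self, error, ok):
        assert success_threshold_check(error) is ok


class TestMomentAlign:
    def test_npc_symmetry_axis_to_z(self, npc_model):
        cloud = dense_npc_cloud(npc_model, per_site=10)
        A = moment_align(cloud)
        aligned = apply_transform(cloud, A)
        # smallest-variance axis on z, centroid at origin
        var = aligned.coords.var(axis=0)
        assert var[2] == pytest.approx(min(var))
        assert np.allclose(aligned.coords.mean(axis=0), 0, atol=1e-9)

    def test_undoes_known_tilt(self, npc_model, rng):
        cloud = dense_npc_cloud(npc_model, per_site=20, noise=1.0, rng=rng)
        tilt = RigidTransform.from_rotvec([np.deg2rad(30), 0, 0])
        A = moment_align(apply_transform(cloud, tilt))
        # the composed net rotation maps z to +-z
        net = A.rotation @ tilt.rotation
        assert abs(abs(net[2, 2]) - 1) < np.deg2rad(0.5)

    def test_returns_valid_transform(self, npc_model):
        A = moment_align(dense_npc_cloud(npc_model))
        assert np.allclose(A.rotation.T @ A.rotation, np.eye(3), atol=1e-9)


class TestRingMeasures:
    def test_ring_distance_noise_free(self, npc_model):
        cloud = dense_npc_cloud(npc_model)
        assert abs(ring_distance(cloud) - 59.0) < 0.5

    def test_ring_distance_two_noisy_planes(self, rng):
        z = np.concatenate([rng.normal(30, 5, 4000), rng.normal(-30, 5, 4000)])
        xy = rng.normal(0, 40, (8000, 2))
        cloud = LocalizationCloud(np.column_stack([xy, z]), 3.0, 9.0)
        assert abs(ring_distance(cloud) - 60.0) < 1.0

    def test_ring_distance_z_shift_invariant(self, npc_model):
        cloud = dense_npc_cloud(npc_model)
        shifted = LocalizationCloud(cloud.coords + [0, 0, 17.0], 3.0, 9.0)
        assert np.isclose(ring_distance(cloud), ring_distance(shifted), atol=1e-9)

    def test_ring_distance_unimodal_raises(self, rng):
        cloud = LocalizationCloud(rng.normal(0, 5, (2000, 3)), 3.0, 9.0)
        with pytest.raises(ValueError):
            ring_distance(cloud)

    def test_ring_radii_noise_free(self, npc_model):
        cloud = dense_npc_cloud(npc_model)
        r_top, r_bot = ring_radii(cloud)
        nominal = (49.7 + 42.7) / 2  # two concentric circles per ring
        assert abs(r_top - nominal) < 1.0
        assert abs(r_bot - nominal) < 1.0

    def test_single_radius_ring_with_noise(self, rng):
        theta = rng.uniform(0, 2 * np.pi, 8000)
        r = 50.0 + rng.normal(0, 3, 8000)
        z = np.concatenate([np.full(4000, 30.0), np.full(4000, -30.0)])
        z = z + rng.normal(0, 2, 8000)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
        rt, rb = ring_radii(LocalizationCloud(pts, 3.0, 9.0))
        assert abs(rt - 50.0) < 1.0 and abs(rb - 50.0) < 1.0


class TestAngularShift:
    def test_noise_free_recovers_configured_shift(self):
        m = make_npc_model(azimuthal_shift=13.0)
        cloud = dense_npc_cloud(m, per_site=200)
        assert abs(angular_shift(cloud) - 13.0) < 0.1

    def test_zero_shift(self):
        m = make_npc_model(azimuthal_shift=0.0)
        cloud = dense_npc_cloud(m, per_site=200)
        assert abs(angular_shift(cloud)) < 0.1

    def test_invariant_under_common_z_rotation(self):
        m = make_npc_model(azimuthal_shift=13.0)
        cloud = dense_npc_cloud(m, per_site=100)
        rot = RigidTransform.from_rotvec([0, 0, np.deg2rad(25)])
        assert np.isclose(angular_shift(cloud),
                          angular_shift(apply_transform(cloud, rot)), atol=0.05)


class TestFsc:
    def test_duplicated_cloud_nyquist_limited(self, npc_model, rng):
        cloud = dense_npc_cloud(npc_model, per_site=30, noise=2.0, rng=rng)
        dup = LocalizationCloud(np.vstack([cloud.coords, cloud.coords]), 3.0, 9.0)
        groups = np.r_[np.zeros(len(cloud)), np.ones(len(cloud))]
        res, (k, fsc) = fsc_resolution(dup, voxel=2.0, groups=groups,
                                       rng=np.random.default_rng(0))
        assert res == 4.0  # never crosses the threshold: 2 * voxel
        assert np.all(fsc >= 0.99)

    def test_independent_uniform_clouds_unresolved(self, rng):
        pts = rng.uniform(-60, 60, (4000, 3))
        cloud = LocalizationCloud(pts, 3.0, 9.0)
        res, (k, fsc) = fsc_resolution(cloud, voxel=4.0,
                                       rng=np.random.default_rng(1))
        assert res > 30.0  # far worse than any structural scale of interest

    def test_fsc_values_bounded(self, npc_model, rng):
        cloud = dense_npc_cloud(npc_model, per_site=20, noise=3.0, rng=rng)
        _, (k, fsc) = fsc_resolution(cloud, voxel=3.0, rng=np.random.default_rng(2))
        assert np.all(fsc <= 1.0 + 1e-9) and np.all(fsc >= -1.0 - 1e-9)


class TestTiltDistribution:
    def test_identity_poses_zero_tilt(self):
        poses = AbsolutePoseSet([RigidTransform.identity() for _ in range(5)])
        out = tilt_distribution(poses)
        assert np.allclose(out["tilt_deg"], 0)

    def test_known_tilt_recovered(self):
        T = RigidTransform.from_rotvec([np.deg2rad(10), 0, 0])
        poses = AbsolutePoseSet([T] * 4)
        out = tilt_distribution(poses)
        assert np.allclose(out["tilt_deg"], 10.0, atol=1e-9)

    def test_range(self, rng):
        poses = AbsolutePoseSet([random_rigid_transform(rng) for _ in range(30)])
        t = tilt_distribution(poses)["tilt_deg"]
        assert np.all((t >= 0) & (t <= 180))
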
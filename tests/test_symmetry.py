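import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from smlmfuse.gmm_registration import PairResult, RelativePoseSet
from smlmfuse.lie_averaging import ConsistencyRecord, consistency, recompute_relative
from smlmfuse.particle_store import RigidTransform
from smlmfuse.symmetry import (
    axis_density,
    detect_fold,
    expected_trace_set,
    fold_relative_by_symmetry,
    group_rotations,
    rotation_axis,
    scramble_symmetric_poses,
)


class TestExpectedTraceSet:
    @pytest.mark.parametrize("n,expected", [
        (2, [3.0, -1.0]),
        (3, [3.0, 0.0]),
        (4, [3.0, 1.0, -1.0]),
        (8, [3.0, 1 + np.sqrt(2), 1.0, 1 - np.sqrt(2), -1.0]),
    ])
    def test_known_sets(self, n, expected):
        assert np.allclose(expected_trace_set(n), sorted(expected, reverse=True))

    def test_values_in_range(self):
        for n in range(1, 13):
            vals = expected_trace_set(n)
            assert np.all(vals <= 3.0 + 1e-12) and np.all(vals >= -1.0 - 1e-12)

    def test_invalid_fold(self):
        with pytest.raises(ValueError):
            expected_trace_set(0)

    def test_matches_explicit_rotation_traces(self):
        for n in (2, 3, 8):
            traces = {round(float(np.trace(g)), 9) for g in
                      group_rotations(n, np.array([0.3, -0.5, 0.9]))}
            assert traces == {round(float(v), 9) for v in expected_trace_set(n)}


def sample_group_traces(n, size, noise, rng):
    k = rng.integers(0, n, size=size)
    return 1 + 2 * np.cos(2 * np.pi * k / n) + rng.normal(0, noise, size)


class TestDetectFold:
    @pytest.mark.parametrize("n", [2, 3, 8])
    def test_recovers_fold_from_noisy_traces(self, n, rng):
        traces = sample_group_traces(n, 500, 0.05, rng)
        report = detect_fold(traces)
        assert report.folds and report.folds[0] == n

    def test_tetrahedral_compound_reports_two_and_three(self, rng):
        t2 = sample_group_traces(2, 300, 0.05, rng)
        t3 = sample_group_traces(3, 300, 0.05, rng)
        report = detect_fold(np.concatenate([t2, t3]))
        assert set(report.folds) == {2, 3}

    def test_no_fold_for_identity_only_traces(self, rng):
        report = detect_fold(3.0 - np.abs(rng.normal(0, 0.03, 300)))
        assert report.folds == []

    def test_small_sample_warns(self, rng):
        report = detect_fold(sample_group_traces(2, 10, 0.05, rng))
        assert report.warning is not None


class TestRotationAxis:
    def test_quarter_turn_about_z(self):
        S = Rotation.from_rotvec([0, 0, np.pi / 2]).as_matrix()
        assert np.allclose(rotation_axis(S), [0, 0, 1], atol=1e-12)

    def test_third_turn_about_x(self):
        S = Rotation.from_rotvec([2 * np.pi / 3, 0, 0]).as_matrix()
        assert np.allclose(rotation_axis(S), [1, 0, 0], atol=1e-12)

    def test_identity_indeterminate(self):
        assert rotation_axis(np.eye(3)) is None

    def test_half_turn_recovered_from_eigenvector(self):
        axis = np.array([1.0, 2.0, -1.0]) / np.sqrt(6)
        S = Rotation.from_rotvec(np.pi * axis).as_matrix()
        out = rotation_axis(S)
        assert abs(abs(out @ axis) - 1) < 1e-9


class TestAxisDensity:
    def test_concentrated_sample_single_maximum(self, rng):
        axes = np.array([0, 0, 1.0]) + rng.normal(0, 0.02, (500, 3))
        _, maxima = axis_density(axes)
        assert len(maxima) == 1
        assert np.degrees(np.arccos(abs(maxima[0][0] @ [0, 0, 1]))) < 2.0

    def test_two_populations_two_maxima(self, rng):
        a = np.array([0, 0, 1.0]) + rng.normal(0, 0.02, (250, 3))
        b = np.array([1.0, 0, 0]) + rng.normal(0, 0.02, (250, 3))
        _, maxima = axis_density(np.vstack([a, b]))
        assert len(maxima) == 2

    def test_antipodal_identification(self, rng):
        axes = np.vstack([np.tile([0, 0, 1.0], (50, 1)),
                          np.tile([0, 0, -1.0], (50, 1))])
        axes = axes + rng.normal(0, 0.02, axes.shape)
        _, maxima = axis_density(axes)
        assert len(maxima) == 1


def records_from_matrices(mats):
    out = []
    for k, S in enumerate(mats):
        out.append(ConsistencyRecord(i=0, j=k + 1, S=S, trace=float(np.trace(S)),
                                     axis=rotation_axis(S)))
    return out


class TestFoldRelativeBySymmetry:
    def test_exact_group_element_folds_to_identity(self):
        axis = np.array([0, 0, 1.0])
        g1 = Rotation.from_rotvec(2 * np.pi / 8 * axis).as_matrix()
        rel = RelativePoseSet(n_particles=2)
        rel.add(PairResult(0, 1, RigidTransform(g1, np.zeros(3)), 1.0))
        recs = records_from_matrices([g1])
        out = fold_relative_by_symmetry(rel, recs, (8, axis))
        folded = out.results[(0, 1)].transform.rotation
        assert np.allclose(folded, np.eye(3), atol=1e-9)

    def test_identity_unchanged(self):
        axis = np.array([0, 0, 1.0])
        rel = RelativePoseSet(n_particles=2)
        rel.add(PairResult(0, 1, RigidTransform.identity(), 1.0))
        recs = records_from_matrices([np.eye(3)])
        out = fold_relative_by_symmetry(rel, recs, (8, axis))
        assert np.allclose(out.results[(0, 1)].transform.rotation, np.eye(3))

    def test_promotion_does_not_lose_pairs(self, rng):
        # relative poses scattered over C8 branches: after folding, the
        # number of trace-consistent pairs can only grow
        axis = np.array([0, 0, 1.0])
        gens = group_rotations(8, axis)
        n = 8
        rel = RelativePoseSet(n_particles=n)
        for i in range(n - 1):
            for j in range(i + 1, n):
                g = gens[rng.integers(0, 8)]
                rel.add(PairResult(i, j, RigidTransform(g, np.zeros(3)), 1.0))
        from smlmfuse.lie_averaging import AbsolutePoseSet

        identity_poses = AbsolutePoseSet([RigidTransform.identity()] * n)
        recs = consistency(rel, recompute_relative(identity_poses))
        kept_before = sum(1 for r in recs if 3 - r.trace <= 0.5)
        out = fold_relative_by_symmetry(rel, recs, (8, axis))
        recs_after = consistency(out, recompute_relative(identity_poses))
        kept_after = sum(1 for r in recs_after if 3 - r.trace <= 0.5)
        assert kept_after >= kept_before
        assert kept_after == len(recs_after)


class TestScramble:
    def test_fold_one_is_noop(self, rng):
        from smlmfuse.lie_averaging import AbsolutePoseSet

        poses = AbsolutePoseSet([RigidTransform.identity()])
        out = scramble_symmetric_poses(poses, (1, np.array([0, 0, 1.0])),
                                       np.random.default_rng(0))
        assert out is poses

    def test_site_set_invariant_under_scramble(self, npc_model, rng):
        from smlmfuse.lie_averaging import AbsolutePoseSet
        from scipy.spatial.distance import cdist

        poses = AbsolutePoseSet([RigidTransform.identity() for _ in range(5)])
        out = scramble_symmetric_poses(poses, (8, np.array([0, 0, 1.0])),
                                       np.random.default_rng(1))
        for p in out.poses:
            moved = npc_model.sites @ p.rotation + p.translation  # p^-1 action
            moved = p.inverse().apply(npc_model.sites)
            assert cdist(moved, npc_model.sites).min(axis=1).max() < 1e-9

    def test_uniform_branch_frequencies(self):
        from smlmfuse.lie_averaging import AbsolutePoseSet

        n_draws = 10_000
        rng = np.random.default_rng(7)
        counts = np.zeros(8)
        poses = AbsolutePoseSet([RigidTransform.identity()])
        for _ in range(n_draws):
            out = scramble_symmetric_poses(poses, (8, np.array([0, 0, 1.0])), rng)
            ang = Rotation.from_matrix(out[0].rotation).as_rotvec()[2]
            k = int(round((ang % (2 * np.pi)) / (np.pi / 4))) % 8
            counts[k] += 1
        p = 1 / 8
        se = np.sqrt(n_draws * p * (1 - p))
        assert np.all(np.abs(counts - n_draws * p) < 3 * se + 1e-9)
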
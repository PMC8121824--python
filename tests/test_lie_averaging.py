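import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from smlmfuse.gmm_registration import PairResult, RelativePoseSet
from smlmfuse.lie_averaging import (
    consistency,
    iterate_averaging,
    l1_average,
    l2_average,
    prune,
    recompute_relative,
    se3_exp,
    se3_log,
)
from smlmfuse.particle_store import RigidTransform
from tests.conftest import random_rigid_transform


def make_consistent_rel(poses, scores=None):
    """Exact relative pose set M_ij = M_j M_i^{-1} from absolute poses."""
    n = len(poses)
    rel = RelativePoseSet(n_particles=n)
    for i in range(n - 1):
        for j in range(i + 1, n):
            s = 1.0 if scores is None else scores[(i, j)]
            rel.add(PairResult(i=i, j=j, transform=poses[j] @ poses[i].inverse(),
                               score=s))
    return rel


def pose_error(est, true):
    """Max rotation error (deg) after fixing the gauge to particle 0."""
    errs = []
    g_est0, g_true0 = est[0].inverse(), true[0].inverse()
    for e, t in zip(est.poses, true):
        d = (e @ g_est0).rotation @ ((t @ g_true0).rotation).T
        errs.append(np.degrees(np.arccos(np.clip((np.trace(d) - 1) / 2, -1, 1))))
    return max(errs)


class TestSe3Maps:
    def test_log_of_identity_is_zero(self):
        assert np.allclose(se3_log(RigidTransform.identity()), 0)

    def test_quarter_turn_closed_form(self):
        T = RigidTransform.from_rotvec([0, 0, np.pi / 2])
        v = se3_log(T)
        assert np.allclose(v[:3], [0, 0, np.pi / 2], atol=1e-12)

    def test_exp_log_round_trip(self, rng):
        for _ in range(20):
            T = random_rigid_transform(rng)
            if np.linalg.norm(Rotation.from_matrix(T.rotation).as_rotvec()) > np.pi - 1e-3:
                continue
            back = se3_exp(se3_log(T))
            assert np.allclose(back.rotation, T.rotation, atol=1e-9)
            assert np.allclose(back.translation, T.translation, atol=1e-9)

    def test_half_turn_raises(self):
        T = RigidTransform.from_rotvec([np.pi, 0, 0])
        with pytest.raises(ValueError):
            se3_log(T)


class TestL1Average:
    def test_exact_recovery_zero_noise(self, rng):
        true = [RigidTransform.identity()] + [random_rigid_transform(rng)
                                              for _ in range(4)]
        rel = make_consistent_rel(true)
        est = l1_average(rel)
        assert pose_error(est, true) < 1e-5

    def test_gauge_fixed_to_first_particle(self, rng):
        true = [random_rigid_transform(rng) for _ in range(4)]
        est = l1_average(make_consistent_rel(true))
        assert np.allclose(est[0].rotation, np.eye(3), atol=1e-9)
        assert np.allclose(est[0].translation, 0, atol=1e-9)

    def test_two_particles_single_pair(self, rng):
        T = random_rigid_transform(rng)
        rel = RelativePoseSet(n_particles=2)
        rel.add(PairResult(i=0, j=1, transform=T, score=1.0))
        est = l1_average(rel)
        assert np.allclose(est[1].rotation, T.rotation, atol=1e-9)
        assert np.allclose(est[1].translation, T.translation, atol=1e-9)

    def test_l1_robust_to_one_corrupted_pair(self, rng):
        # one corrupted pair among N=6: L1 recovers near-exactly, plain
        # least squares errs by at least 10x more
        true = [RigidTransform.identity()] + [random_rigid_transform(rng)
                                              for _ in range(5)]
        rel = make_consistent_rel(true)
        rel.results[(1, 2)] = PairResult(i=1, j=2,
                                         transform=random_rigid_transform(rng),
                                         score=1.0)
        e_l1 = pose_error(l1_average(rel), true)
        e_l2 = pose_error(l2_average(rel), true)
        assert e_l1 < 1e-3 * 180 / np.pi  # well below a milliradian
        assert e_l2 > 10 * max(e_l1, 1e-9)

    def test_disconnected_graph_raises(self, rng):
        rel = RelativePoseSet(n_particles=4)
        rel.add(PairResult(i=0, j=1, transform=random_rigid_transform(rng), score=1.0))
        rel.add(PairResult(i=2, j=3, transform=random_rigid_transform(rng), score=1.0))
        with pytest.raises(ValueError, match="disconnected"):
            l1_average(rel)


class TestRecomputeAndConsistency:
    def test_identity_poses_give_identity_relatives(self):
        from smlmfuse.lie_averaging import AbsolutePoseSet

        poses = AbsolutePoseSet([RigidTransform.identity() for _ in range(3)])
        rel = recompute_relative(poses)
        for res in rel.pairs():
            assert np.allclose(res.transform.rotation, np.eye(3))

    def test_cycle_consistency_by_construction(self, rng):
        from smlmfuse.lie_averaging import AbsolutePoseSet

        poses = AbsolutePoseSet([random_rigid_transform(rng) for _ in range(4)])
        rel = recompute_relative(poses)
        M01 = rel.results[(0, 1)].transform
        M12 = rel.results[(1, 2)].transform
        M02 = rel.results[(0, 2)].transform
        assert np.allclose((M12 @ M01).rotation, M02.rotation, atol=1e-9)

    def test_perfect_pair_trace_three(self, rng):
        true = [random_rigid_transform(rng) for _ in range(3)]
        rel = make_consistent_rel(true)
        est = l1_average(rel)
        records = consistency(rel, recompute_relative(est))
        for r in records:
            assert np.isclose(r.trace, 3.0, atol=1e-6)

    def test_half_turn_mismatch_gives_trace_minus_one(self, rng):
        true = [random_rigid_transform(rng) for _ in range(2)]
        rel = make_consistent_rel(true)
        flip = RigidTransform.from_rotvec([np.pi * 0.999999, 0, 0])
        rel.results[(0, 1)] = PairResult(
            i=0, j=1, transform=rel.results[(0, 1)].transform @ flip, score=1.0)
        from smlmfuse.lie_averaging import AbsolutePoseSet

        records = consistency(rel, recompute_relative(AbsolutePoseSet(
            [RigidTransform.identity(), true[1] @ true[0].inverse()])))
        # wait: recomputed must equal the uncorrupted relatives
        assert records[0].trace < -0.99

    def test_traces_bounded(self, rng):
        true = [random_rigid_transform(rng) for _ in range(5)]
        rel = make_consistent_rel(true)
        for key in list(rel.results):
            if rng.random() < 0.5:
                rel.results[key] = PairResult(key[0], key[1],
                                              random_rigid_transform(rng), 1.0)
        records = consistency(rel, recompute_relative(l1_average(rel)))
        for r in records:
            assert -1.0 - 1e-9 <= r.trace <= 3.0 + 1e-9


class TestPrune:
    def test_nothing_pruned_when_consistent(self, rng):
        true = [random_rigid_transform(rng) for _ in range(4)]
        rel = make_consistent_rel(true)
        records = consistency(rel, recompute_relative(l1_average(rel)))
        prune(rel, records, epsilon=0.5)
        assert rel.n_kept() == 6

    def test_bad_pair_pruned(self, rng):
        true = [random_rigid_transform(rng) for _ in range(4)]
        rel = make_consistent_rel(true)
        flip = RigidTransform.from_rotvec([3.0, 0, 0])
        rel.results[(0, 3)] = PairResult(0, 3, rel.results[(0, 3)].transform @ flip, 1.0)
        est = l1_average(rel)
        records = consistency(rel, recompute_relative(est))
        prune(rel, records, epsilon=0.5)
        assert not rel.mask[(0, 3)]
        assert rel.n_kept() == 5

    def test_connectivity_repair_restores_best_edge(self, rng):
        # star graph: node 3 attaches only through one (corrupted) edge, so
        # pruning would isolate it; the repair must restore that edge
        true = [random_rigid_transform(rng) for _ in range(4)]
        rel = RelativePoseSet(n_particles=4)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            rel.add(PairResult(i, j, true[j] @ true[i].inverse(), score=1.0))
        bad = true[3] @ true[0].inverse() @ RigidTransform.from_rotvec([2.0, 0, 0])
        rel.add(PairResult(0, 3, bad, score=1.0))
        est = l1_average(rel)
        records = consistency(rel, recompute_relative(est))
        prune(rel, records, epsilon=0.5)
        assert rel.mask[(0, 3)]  # restored to keep the graph connected
        assert rel.n_kept() == 4


class TestIterateAveraging:
    def test_consistent_input_matches_single_average(self, rng):
        true = [random_rigid_transform(rng) for _ in range(5)]
        rel = make_consistent_rel(true)
        direct = l1_average(make_consistent_rel(true))
        iterated, history = iterate_averaging(rel, n_iter=2)
        assert pose_error(iterated, [p for p in direct.poses]) < 1e-6
        assert len(history) == 2
        for records in history:
            assert len(records) == 10

    def test_corrupted_pairs_cleaned_up(self, rng):
        # 20% corrupted pairs on N=10: error after 2 iterations does not
        # exceed the single-iteration error
        true = [random_rigid_transform(rng) for _ in range(10)]
        rel1 = make_consistent_rel(true)
        keys = list(rel1.results)
        bad = [keys[k] for k in rng.choice(len(keys), size=9, replace=False)]
        for key in bad:
            rel1.results[key] = PairResult(key[0], key[1],
                                           random_rigid_transform(rng), 1.0)
        import copy

        rel2 = copy.deepcopy(rel1)
        est1, _ = iterate_averaging(rel1, n_iter=1)
        est2, _ = iterate_averaging(rel2, n_iter=2)
        assert pose_error(est2, true) <= pose_error(est1, true) + 1e-9

    def test_gauge_covariance_of_traces(self, rng):
        # pre-composing all ground-truth poses with one global transform
        # leaves every consistency trace unchanged
        # changing the common frame (right-composing every true pose with a
        # global transform) leaves the relative transforms, and hence all
        # consistency traces, unchanged
        true = [random_rigid_transform(rng) for _ in range(5)]
        G = random_rigid_transform(rng)
        moved = [T @ G for T in true]
        rel_a = make_consistent_rel(true)
        rel_b = make_consistent_rel(moved)
        for key in rel_a.results:
            if rng.random() < 0.3:
                bad = random_rigid_transform(rng)
                rel_a.results[key] = PairResult(*key, bad, 1.0)
                rel_b.results[key] = PairResult(*key, bad, 1.0)
        rec_a = consistency(rel_a, recompute_relative(l1_average(rel_a)))
        rec_b = consistency(rel_b, recompute_relative(l1_average(rel_b)))
        for ra, rb in zip(rec_a, rec_b):
            assert np.isclose(ra.trace, rb.trace, atol=1e-5)
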
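"""Robust averaging of relative poses on SE(3).

The N(N-1)/2 noisy pairwise registrations M_ij are turned into N absolute
poses M_i by iteratively re-weighted averaging in the Lie algebra se(3),
approximating an L1 objective for robustness against erroneous registrations.
Poses follow the convention M_ij = M_j ∘ M_i^{-1} (the pose M_i maps the
common frame onto particle i; the gauge is fixed by M_0 = identity).

After averaging, the recomputed relative rotations R̂_ij are compared with
the measured ones through the consistency matrix S_ij = R_ij (R̂_ij)^{-1};
its trace (= 1 + 2 cos ψ_ij) is 3 for a perfect pair and the basis both for
pruning bad registrations and for symmetry detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from smlmfuse.gmm_registration import PairResult, RelativePoseSet
from smlmfuse.particle_store import RigidTransform

_CUT_LOCUS_TOL = 1e-6


@dataclass
class ConsistencyRecord:
    """Per-pair rotation-consistency summary S_ij = R_ij (R̂_ij)^{-1}."""

    i: int
    j: int
    S: np.ndarray
    trace: float
    axis: np.ndarray | None
    kept: bool = True


@dataclass
class AbsolutePoseSet:
    """N absolute poses M_i, defined up to one global rigid transform
    (gauge: the reference particle's pose is the identity)."""

    poses: list[RigidTransform]
    reference: int = 0
    note: str = "poses defined up to a global rigid transform; gauge M_ref = I"

    def __len__(self) -> int:
        return len(self.poses)

    def __getitem__(self, i: int) -> RigidTransform:
        return self.poses[i]


def se3_log(T: RigidTransform) -> np.ndarray:
    """Logarithm map SE(3) -> se(3) as a 6-vector (rotation vector, v).

    Raises for rotations within 1e-6 of a half turn, where the log branch is
    ambiguous.
    """
    rot = Rotation.from_matrix(T.rotation)
    w = rot.as_rotvec()
    theta = np.linalg.norm(w)
    if theta >= np.pi - _CUT_LOCUS_TOL:
        raise ValueError("rotation angle at the cut locus (within 1e-6 of pi); log branch ambiguous")
    V = _se3_V(w)
    v = np.linalg.solve(V, T.translation)
    return np.concatenate([w, v])


def se3_exp(vec: np.ndarray) -> RigidTransform:
    """Exponential map se(3) -> SE(3) from a 6-vector (rotation vector, v)."""
    vec = np.asarray(vec, dtype=float)
    w, v = vec[:3], vec[3:]
    R = Rotation.from_rotvec(w).as_matrix()
    return RigidTransform(R, _se3_V(w) @ v)


def _skew(w: np.ndarray) -> np.ndarray:
    return np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])


def _se3_V(w: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(w)
    W = _skew(w)
    if theta < 1e-8:
        return np.eye(3) + 0.5 * W + W @ W / 6.0
    return (np.eye(3) + (1 - np.cos(theta)) / theta**2 * W
            + (theta - np.sin(theta)) / theta**3 * (W @ W))


def _edge_residual(M_ij: RigidTransform, M_i: RigidTransform,
                   M_j: RigidTransform) -> np.ndarray | None:
    """log(M_j^{-1} M_ij M_i); None at the rotation cut locus (treated as outlier)."""
    try:
        return se3_log(M_j.inverse() @ M_ij @ M_i)
    except ValueError:
        return None


def _spanning_tree_init(rel: RelativePoseSet) -> list[RigidTransform]:
    """Initial poses from a maximum-score spanning tree rooted at particle 0."""
    n = rel.n_particles
    adj: dict[int, list] = {i: [] for i in range(n)}
    for res in rel.pairs(kept_only=True):
        adj[res.i].append((res.score, res.j, res, True))
        adj[res.j].append((res.score, res.i, res, False))
    poses: list[RigidTransform | None] = [None] * n
    poses[0] = RigidTransform.identity()
    # Prim's algorithm, always extending along the best-scoring edge
    import heapq

    heap = [(-s, 0, nbr, res, fwd) for s, nbr, res, fwd in adj[0]]
    heapq.heapify(heap)
    while heap:
        negs, src, dst, res, fwd = heapq.heappop(heap)
        if poses[dst] is not None:
            continue
        # fwd: edge measured i->j with src == i  =>  M_dst = M_ij ∘ M_src
        M = res.transform
        poses[dst] = (M @ poses[src]) if fwd else (M.inverse() @ poses[src])
        for s, nbr, r2, f2 in adj[dst]:
            if poses[nbr] is None:
                heapq.heappush(heap, (-s, dst, nbr, r2, f2))
    if any(p is None for p in poses):
        missing = [i for i, p in enumerate(poses) if p is None]
        raise ValueError(f"registration graph is disconnected; unreachable particles: {missing}")
    return poses  # type: ignore[return-value]


def l1_average(rel: RelativePoseSet, norm: str = "l1",
               translation_scale: float | None = None,
               max_iter: int = 100, tol: float = 1e-12) -> AbsolutePoseSet:
    """Absolute poses from relative ones by robust averaging in se(3).

    Minimizes sum over kept pairs of ||log(M_ij^{-1} M_j M_i^{-1})|| by
    Weiszfeld-style iteratively re-weighted least squares in the tangent
    space, initialized from a maximum-score spanning tree.  ``norm="l2"``
    keeps unit weights (plain least squares), provided as the non-robust
    comparator.  Rotations are in radians; translations are balanced against
    them through ``translation_scale`` (nm per radian; default: median
    translation magnitude of the input, floored at 1 nm).
    """
    if norm not in ("l1", "l2"):
        raise ValueError("norm must be 'l1' or 'l2'")
    edges = list(rel.pairs(kept_only=True))
    if not edges:
        raise ValueError("no kept pairs to average")
    poses = _spanning_tree_init(rel)
    n = rel.n_particles
    if translation_scale is None:
        mags = [np.linalg.norm(e.transform.translation) for e in edges]
        translation_scale = max(float(np.median(mags)), 1.0)
    scale_vec = np.array([1.0, 1.0, 1.0] + [1.0 / translation_scale] * 3)

    for _ in range(max_iter):
        rows, resids, weights = [], [], []
        for e in edges:
            v = _edge_residual(e.transform, poses[e.i], poses[e.j])
            if v is None:
                continue  # cut-locus pair: exclude from this update
            rows.append((e.i, e.j))
            resids.append(v)
            if norm == "l1":
                weights.append(1.0 / max(np.linalg.norm(v * scale_vec), 1e-6))
            else:
                weights.append(1.0)
        if not rows:
            break
        V = np.asarray(resids)
        W = np.asarray(weights)
        # weighted LS for delta in: delta_i - delta_j + v = 0, delta_0 = 0
        L = np.zeros((n, n))
        B = np.zeros((n, 6))
        for (i, j), v, w in zip(rows, V, W):
            L[i, i] += w
            L[j, j] += w
            L[i, j] -= w
            L[j, i] -= w
            B[i] -= w * v
            B[j] += w * v
        free = np.arange(1, n)
        delta = np.zeros((n, 6))
        delta[free] = np.linalg.solve(L[np.ix_(free, free)] + 1e-12 * np.eye(n - 1),
                                      B[free])
        step = np.abs(delta).max()
        poses = [poses[k] @ se3_exp(delta[k]) for k in range(n)]
        if step < tol:
            break
    # re-fix the gauge exactly: right-multiply all poses by M_0^{-1}
    g = poses[0].inverse()
    poses = [p @ g for p in poses]
    return AbsolutePoseSet(poses)


def l2_average(rel: RelativePoseSet, **kwargs) -> AbsolutePoseSet:
    """Plain (non-robust) least-squares pose averaging; comparator for l1_average."""
    return l1_average(rel, norm="l2", **kwargs)


def recompute_relative(abs_poses: AbsolutePoseSet) -> RelativePoseSet:
    """Cycle-consistent relative transforms M̂_ij = M_j ∘ M_i^{-1} for all pairs."""
    n = len(abs_poses)
    rel = RelativePoseSet(n_particles=n)
    for i in range(n - 1):
        for j in range(i + 1, n):
            T = abs_poses[j] @ abs_poses[i].inverse()
            rel.add(PairResult(i=i, j=j, transform=T, score=0.0))
    return rel


def rotation_axis_of(S: np.ndarray, tol: float = 1e-8) -> np.ndarray | None:
    """Rotation axis of S from the antisymmetric part (u = (s32-s23, s13-s31,
    s21-s12)); None when indeterminate by this formula (identity-like), and
    recovered from the +1 eigenvector for half turns."""
    u = np.array([S[2, 1] - S[1, 2], S[0, 2] - S[2, 0], S[1, 0] - S[0, 1]])
    nu = np.linalg.norm(u)
    if nu > tol:
        return u / nu
    if np.trace(S) > 0:  # close to the identity: axis indeterminate
        return None
    # half turn: axis is the eigenvector of S with eigenvalue +1
    vals, vecs = np.linalg.eigh(0.5 * (S + S.T))
    axis = vecs[:, np.argmax(vals)]
    return axis / np.linalg.norm(axis)


def consistency(rel_measured: RelativePoseSet,
                rel_recomputed: RelativePoseSet) -> list[ConsistencyRecord]:
    """Per-pair consistency matrices S_ij = R_ij (R̂_ij)^{-1} with trace and axis.

    Records are produced for every measured pair (kept or not) that has a
    recomputed counterpart.
    """
    records = []
    for res in rel_measured.pairs(kept_only=False):
        key = (res.i, res.j)
        if key not in rel_recomputed.results:
            continue
        R = res.transform.rotation
        Rhat = rel_recomputed.results[key].transform.rotation
        S = R @ Rhat.T
        records.append(ConsistencyRecord(
            i=res.i, j=res.j, S=S, trace=float(np.trace(S)),
            axis=rotation_axis_of(S), kept=rel_measured.mask.get(key, False)))
    return records


def _components(n: int, edges: list[tuple[int, int]]) -> list[set[int]]:
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    comps: dict[int, set[int]] = {}
    for k in range(n):
        comps.setdefault(find(k), set()).add(k)
    return list(comps.values())


def prune(rel: RelativePoseSet, records: list[ConsistencyRecord],
          epsilon: float = 0.5) -> RelativePoseSet:
    """Mask pairs whose consistency trace deviates from 3 by more than epsilon.

    The empirical threshold epsilon = 0.5 removes inconsistent registrations
    while keeping the peak at trace = 3.  If masking disconnects the
    registration graph, the lowest-deviation masked edges are restored per
    component until the graph is connected again.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    by_pair = {(r.i, r.j): r for r in records}
    for key in rel.mask:
        r = by_pair.get(key)
        if r is not None:
            rel.mask[key] = (3.0 - r.trace) <= epsilon
            r.kept = rel.mask[key]
    # connectivity repair
    while True:
        kept_edges = [k for k, v in rel.mask.items() if v]
        comps = _components(rel.n_particles, kept_edges)
        if len(comps) <= 1:
            break
        comp0 = comps[0]
        candidates = []
        for key, kept in rel.mask.items():
            if kept or key not in by_pair:
                continue
            i, j = key
            if (i in comp0) != (j in comp0):
                candidates.append((3.0 - by_pair[key].trace, key))
        if not candidates:
            raise ValueError(f"registration graph cannot be reconnected; components: {comps}")
        _, best = min(candidates)
        rel.mask[best] = True
        by_pair[best].kept = True
    return rel


def iterate_averaging(rel: RelativePoseSet, epsilon: float = 0.5,
                      n_iter: int = 2, **avg_kwargs):
    """Alternate robust averaging, relative-pose recomputation, consistency
    checking and pruning; two iterations yield the data-driven template poses.

    Returns ``(AbsolutePoseSet, history)`` where history is the list of
    per-iteration ConsistencyRecord lists (the raw material for symmetry
    detection).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    history = []
    poses = None
    for _ in range(n_iter):
        poses = l1_average(rel, **avg_kwargs)
        rel_hat = recompute_relative(poses)
        records = consistency(rel, rel_hat)
        history.append(records)
        rel = prune(rel, records, epsilon)
    poses = l1_average(rel, **avg_kwargs)
    return poses, history
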
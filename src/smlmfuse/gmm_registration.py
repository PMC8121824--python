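"""Pairwise rigid registration of localization clouds.

Each cloud is modeled as a Gaussian mixture with one component per
localization.  Registration minimizes the L2 distance between the two
isotropic mixtures (closed form for Gaussians) from many rotational starts
spread over SO(3); the candidate transforms are then ranked by an anisotropic
Bhattacharyya overlap score that accounts for the 2-4x worse axial precision,
and the best is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from smlmfuse.particle_store import LocalizationCloud, ParticleSet, RigidTransform


@dataclass
class PairResult:
    """Outcome of registering particle i onto particle j.

    ``alt_transform``/``alt_score`` hold the best-scoring rival candidate
    whose rotation is well separated from the winner — the other plausible
    branch when the registration is ambiguous (None when all candidates
    agree on the orientation).
    """

    i: int
    j: int
    transform: RigidTransform
    score: float
    n_starts: int = 1
    converged: bool = True
    alt_transform: RigidTransform | None = None
    alt_score: float = 0.0

    def __post_init__(self) -> None:
        if not self.i < self.j:
            raise ValueError("PairResult requires i < j")
        if not np.isfinite(self.score):
            raise ValueError("score must be finite")


@dataclass
class RotationGrid:
    """Deterministic set of rotations approximately uniform over SO(3)."""

    rotations: list[RigidTransform]
    resolution: int = 0

    def __len__(self) -> int:
        return len(self.rotations)


@dataclass
class RelativePoseSet:
    """Upper-triangular collection of the N(N-1)/2 pairwise transforms M_ij."""

    n_particles: int
    results: dict = field(default_factory=dict)  # (i, j) -> PairResult
    mask: dict = field(default_factory=dict)     # (i, j) -> kept?

    def add(self, res: PairResult) -> None:
        self.results[(res.i, res.j)] = res
        self.mask[(res.i, res.j)] = True

    def pairs(self, kept_only: bool = True):
        for key in sorted(self.results):
            if not kept_only or self.mask.get(key, False):
                yield self.results[key]

    def n_kept(self) -> int:
        return sum(bool(v) for v in self.mask.values())


def _halton(n: int, base: int) -> np.ndarray:
    """Deterministic low-discrepancy sequence in [0, 1)."""
    out = np.empty(n)
    for i in range(n):
        f, r, idx = 1.0, 0.0, i + 1
        while idx > 0:
            f /= base
            r += f * (idx % base)
            idx //= base
        out[i] = r
    return out


def sample_so3(n: int = 576) -> RotationGrid:
    """Low-discrepancy deterministic cover of SO(3) with n rotations.

    Uses super-Fibonacci spirals (a quaternion analogue of the Fibonacci
    sphere) which give near-optimal covering uniformity; the first element
    is replaced by the identity.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rotations = [RigidTransform.identity()]
    if n > 1:
        phi = np.sqrt(2.0)
        psi = 1.533751168755204288118041
        i = np.arange(n - 1, dtype=float)
        s = i + 0.5
        t = s / (n - 1)
        d = 2 * np.pi * s
        r, big_r = np.sqrt(t), np.sqrt(1.0 - t)
        alpha, beta = d / phi, d / psi
        quats = np.column_stack([r * np.sin(alpha), r * np.cos(alpha),
                                 big_r * np.sin(beta), big_r * np.cos(beta)])
        for q in quats:
            rotations.append(RigidTransform(Rotation.from_quat(q).as_matrix(), np.zeros(3)))
    return RotationGrid(rotations, resolution=n)


def local_rotation_grid(n: int, max_angle_rad: float) -> RotationGrid:
    """Deterministic rotations within a geodesic ball of radius max_angle_rad
    about the identity (used to warm-start template re-registration)."""
    rotations = [RigidTransform.identity()]
    if n > 1:
        u = np.column_stack([_halton(n - 1, 2), _halton(n - 1, 3), _halton(n - 1, 5)])
        # map cube to ball: direction from first two coords, radius from third
        theta = np.arccos(1 - 2 * u[:, 0])
        phi = 2 * np.pi * u[:, 1]
        r = max_angle_rad * u[:, 2] ** (1 / 3)
        axes = np.column_stack([np.sin(theta) * np.cos(phi),
                                np.sin(theta) * np.sin(phi), np.cos(theta)])
        for ax, ang in zip(axes, r):
            rotations.append(RigidTransform.from_rotvec(ax * ang))
    return RotationGrid(rotations, resolution=n)


def select_scale(a: LocalizationCloud, b: LocalizationCloud,
                 clamp: tuple[float, float] = (2.0, 30.0)) -> float:
    """Automatic isotropic Gaussian width for GMM registration.

    The scale follows the shape of the particle: it is the median
    nearest-neighbor distance pooled over both clouds, clamped to a
    plausible range of localization-cluster sizes.
    """
    dists = []
    for cloud in (a, b):
        if len(cloud) < 2:
            continue
        d, _ = cKDTree(cloud.coords).query(cloud.coords, k=2)
        dists.append(d[:, 1])
    if not dists:
        return clamp[0]
    scale = float(np.median(np.concatenate(dists)))
    return float(np.clip(scale, *clamp))


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])


def _right_jacobian(w: np.ndarray) -> np.ndarray:
    """Right Jacobian of SO(3) at rotation vector w."""
    theta = np.linalg.norm(w)
    W = _skew(w)
    if theta < 1e-8:
        return np.eye(3) - 0.5 * W + W @ W / 6.0
    return (np.eye(3) - (1 - np.cos(theta)) / theta**2 * W
            + (theta - np.sin(theta)) / theta**3 * (W @ W))


try:
    from numba import njit

    @njit(cache=False, fastmath=True)
    def _gmm_kernel(params, a, b, scale):  # pragma: no cover - via wrapper
        w = params[:3]
        t = params[3:]
        theta2 = w[0] * w[0] + w[1] * w[1] + w[2] * w[2]
        theta = np.sqrt(theta2)
        # Rodrigues: R = I + s1*W + s2*W^2 with W = [w]x
        if theta < 1e-10:
            s1, s2 = 1.0, 0.5
            j1, j2 = 0.5, 1.0 / 6.0
        else:
            s1 = np.sin(theta) / theta
            s2 = (1.0 - np.cos(theta)) / theta2
            j1 = s2                      # (1-cos)/theta^2
            j2 = (theta - np.sin(theta)) / (theta2 * theta)
        W = np.zeros((3, 3))
        W[0, 1], W[0, 2] = -w[2], w[1]
        W[1, 0], W[1, 2] = w[2], -w[0]
        W[2, 0], W[2, 1] = -w[1], w[0]
        W2 = W @ W
        R = np.eye(3) + s1 * W + s2 * W2
        Jr = np.eye(3) - j1 * W + j2 * W2
        inv4s2 = 1.0 / (4.0 * scale * scale)
        P, Q = a.shape[0], b.shape[0]
        y = a @ R.T
        cost = 0.0
        acc = np.zeros(3)      # sum_p a_p x (R^T g_p)
        grad_t = np.zeros(3)
        for p in range(P):
            g0 = 0.0
            g1 = 0.0
            g2 = 0.0
            y0 = y[p, 0] + t[0]
            y1 = y[p, 1] + t[1]
            y2 = y[p, 2] + t[2]
            for q in range(Q):
                d0 = y0 - b[q, 0]
                d1 = y1 - b[q, 1]
                d2 = y2 - b[q, 2]
                e = np.exp(-(d0 * d0 + d1 * d1 + d2 * d2) * inv4s2)
                cost -= e
                g0 += e * d0
                g1 += e * d1
                g2 += e * d2
            c = 2.0 * scale * scale
            g0, g1, g2 = g0 / c, g1 / c, g2 / c
            grad_t[0] += g0
            grad_t[1] += g1
            grad_t[2] += g2
            r0 = R[0, 0] * g0 + R[1, 0] * g1 + R[2, 0] * g2
            r1 = R[0, 1] * g0 + R[1, 1] * g1 + R[2, 1] * g2
            r2 = R[0, 2] * g0 + R[1, 2] * g1 + R[2, 2] * g2
            acc[0] += a[p, 1] * r2 - a[p, 2] * r1
            acc[1] += a[p, 2] * r0 - a[p, 0] * r2
            acc[2] += a[p, 0] * r1 - a[p, 1] * r0
        grad = np.empty(6)
        grad[:3] = Jr.T @ acc
        grad[3:] = grad_t
        return cost, grad

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _gmm_cost_grad(params: np.ndarray, a: np.ndarray, b: np.ndarray,
                   scale: float) -> tuple[float, np.ndarray]:
    """Negative GMM cross-correlation and its gradient on the (rotvec, t) chart.

    Minimizing the mixture L2 distance is equivalent to maximizing the cross
    term sum_pq exp(-||R a_p + t - b_q||^2 / (4 scale^2)) because the self
    terms are rigid-motion invariant.
    """
    if _HAVE_NUMBA:
        cost, grad = _gmm_kernel(np.ascontiguousarray(params, dtype=np.float64),
                                 a, b, float(scale))
        return cost, grad
    w, t = params[:3], params[3:]
    R = Rotation.from_rotvec(w).as_matrix()
    y = a @ R.T + t
    diff = y[:, None, :] - b[None, :, :]
    sq = np.einsum("pqk,pqk->pq", diff, diff)
    E = np.exp(-sq / (4 * scale**2))
    cost = -E.sum()
    # d cost / d y_p = sum_q E_pq * diff_pq / (2 scale^2)
    g = np.einsum("pq,pqk->pk", E, diff) / (2 * scale**2)
    grad_t = g.sum(axis=0)
    # d(R(w) a)/dw = -R [a]x Jr(w)  =>  grad_w = Jr^T sum_p a_p x (R^T g_p)
    RTg = g @ R
    grad_w = _right_jacobian(w).T @ np.cross(a, RTg).sum(axis=0)
    return cost, np.concatenate([grad_w, grad_t])


def gmm_rigid_register(a: LocalizationCloud, b: LocalizationCloud, scale: float,
                       init: RigidTransform | None = None,
                       max_iter: int = 100) -> RigidTransform:
    """Locally optimal rigid transform mapping cloud a into b's frame by
    minimizing the L2 distance between their isotropic GMMs (common width
    ``scale``), starting from ``init``."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    if init is None:
        init = RigidTransform.identity()
    T, _, _ = _gmm_register_raw(a.coords, b.coords, scale, init, max_iter)
    return T


def _gmm_register_raw(a: np.ndarray, b: np.ndarray, scale: float,
                      init: RigidTransform, max_iter: int):
    w0 = Rotation.from_matrix(init.rotation).as_rotvec()
    x0 = np.concatenate([w0, init.translation])
    res = minimize(_gmm_cost_grad, x0, args=(a, b, scale), jac=True,
                   method="L-BFGS-B",
                   options={"maxiter": max_iter, "gtol": 1e-8})
    w, t = res.x[:3], res.x[3:]
    T = RigidTransform(Rotation.from_rotvec(w).as_matrix(), t)
    return T, float(res.fun), bool(res.success)


def _pair_covariances(cloud: LocalizationCloud, extra_rotation: np.ndarray | None = None):
    cov = cloud.covariances()
    if extra_rotation is not None:
        cov = np.einsum("ab,nbc,dc->nad", extra_rotation, cov, extra_rotation)
    return cov


def bhattacharyya_cost(a: LocalizationCloud, b: LocalizationCloud,
                       T: RigidTransform) -> float:
    """Sum of pairwise Bhattacharyya coefficients between the anisotropic
    Gaussian mixtures of cloud a (transformed by T) and cloud b.

    Each localization is a Gaussian with covariance diag(s_lat^2, s_lat^2,
    s_ax^2) rotated by its particle's accumulated orientation; higher scores
    mean better overlap.  Invariant under a common rigid motion of both
    clouds.
    """
    ya = T.apply(a.coords)
    Ca = _pair_covariances(a, T.rotation)
    Cb = b.covariances()
    S = 0.5 * (Ca[:, None, :, :] + Cb[None, :, :, :])  # (P, Q, 3, 3)
    diff = ya[:, None, :] - b.coords[None, :, :]
    Sinv = np.linalg.inv(S)
    maha = np.einsum("pqa,pqab,pqb->pq", diff, Sinv, diff)
    det_s = np.linalg.det(S)
    det_a = np.linalg.det(Ca)
    det_b = np.linalg.det(Cb)
    log_term = 0.5 * (np.log(det_s) - 0.5 * (np.log(det_a)[:, None] + np.log(det_b)[None, :]))
    return float(np.exp(-(maha / 8.0 + log_term)).sum())


def register_pair(a: LocalizationCloud, b: LocalizationCloud, grid: RotationGrid,
                  scale: float | None = None, i: int = 0, j: int = 1,
                  coarse_iter: int = 12, refine_top: int = 5,
                  max_iter: int = 100,
                  init_transforms: list[RigidTransform] | None = None,
                  return_candidates: bool = False):
    """Multi-start GMM registration of a onto b with Bhattacharyya selection.

    Every grid rotation (applied about the centroid-matched configuration)
    seeds a short GMM optimization at a coarse, shape-level scale (so each
    start reaches its basin across the whole structure); the most promising
    candidates are then refined at the requested scale and scored with the
    anisotropic Bhattacharyya cost, and the best-scoring transform wins.
    With ``return_candidates`` the refined (score, transform) list is
    returned alongside, best first — used to judge how ambiguous a
    registration is.
    """
    if scale is None:
        scale = select_scale(a, b)
    ca, cb = a.centroid(), b.centroid()
    # coarse scale ~ 1/16 of the structure extent: wide enough basins for the
    # rotation grid spacing without washing out orientation-discriminating
    # detail
    extent = float(np.linalg.norm(np.ptp(np.vstack([a.coords, b.coords]), axis=0)))
    coarse_scale = max(scale, extent / 16.0)
    inits = init_transforms
    if inits is None:
        inits = []
        for g in grid.rotations:
            R = g.rotation
            inits.append(RigidTransform(R, cb - R @ ca))
    # stage 1: coarse optimization from every start, ranked by a single
    # fine-scale cost evaluation
    stage1 = []
    for T0 in inits:
        T, _, _ = _gmm_register_raw(a.coords, b.coords, coarse_scale, T0, coarse_iter)
        w = Rotation.from_matrix(T.rotation).as_rotvec()
        cost, _ = _gmm_cost_grad(np.concatenate([w, T.translation]),
                                 a.coords, b.coords, scale)
        stage1.append((cost, T))
    stage1.sort(key=lambda ct: ct[0])
    n_refine = min(max(refine_top, 1), len(stage1))
    # stage 2: full refinement of the best coarse candidates, pick by
    # anisotropic Bhattacharyya overlap
    refine = list(stage1[:n_refine])
    if len(stage1) > n_refine:
        # guarantee a well-separated rival so ambiguity can be judged: add
        # the best coarse candidate rotationally far from the cost-best one
        R_best = stage1[0][1].rotation
        for cost, T in stage1[n_refine:]:
            tr = np.trace(T.rotation @ R_best.T)
            if np.degrees(np.arccos(np.clip((tr - 1) / 2, -1, 1))) > 60.0:
                refine.append((cost, T))
                break
    candidates = []
    converged_map = {}
    for cost, T in refine:
        Tr, _, ok = _gmm_register_raw(a.coords, b.coords, scale, T, max_iter)
        score = bhattacharyya_cost(a, b, Tr)
        candidates.append((score, Tr))
        converged_map[id(Tr)] = ok
    if not candidates:
        raise RuntimeError(f"all {len(inits)} registration starts failed for pair ({i}, {j})")
    candidates.sort(key=lambda st: -st[0])
    best_score, best_T = candidates[0]
    alt_T, alt_s = None, 0.0
    for sc, T in candidates[1:]:
        tr = np.trace(T.rotation @ best_T.rotation.T)
        if np.degrees(np.arccos(np.clip((tr - 1) / 2, -1, 1))) > 60.0:
            alt_T, alt_s = T, sc
            break
    result = PairResult(i=i, j=j, transform=best_T, score=best_score,
                        n_starts=len(inits), converged=converged_map[id(best_T)],
                        alt_transform=alt_T, alt_score=alt_s)
    if return_candidates:
        return result, candidates
    return result


def all_to_all(ps: ParticleSet, grid: RotationGrid,
               scale: float | str = "auto", n_jobs: int = 1,
               **pair_kwargs) -> RelativePoseSet:
    """All N(N-1)/2 pairwise registrations of a particle set.

    Results are independent of evaluation order and deterministic for a fixed
    grid (also with ``n_jobs`` > 1, which parallelizes over pairs with
    joblib).  ``scale`` is either a number (nm) or "auto" for per-pair
    automatic selection.
    """
    n = len(ps)
    if n < 2:
        raise ValueError("need at least 2 particles")
    s = None if scale == "auto" else float(scale)
    pairs = [(i, j) for i in range(n - 1) for j in range(i + 1, n)]
    if n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(
            delayed(register_pair)(ps[i], ps[j], grid, scale=s, i=i, j=j,
                                   **pair_kwargs)
            for i, j in pairs)
    else:
        results = [register_pair(ps[i], ps[j], grid, scale=s, i=i, j=j,
                                 **pair_kwargs) for i, j in pairs]
    rel = RelativePoseSet(n_particles=n)
    for res in results:
        rel.add(res)
    return rel
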
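"""Rotational symmetry-group detection from registration consistency records.

For an n-fold symmetric structure the consistency matrices S_ij cluster
around the symmetry rotations, so the histogram of trace(S_ij) = 1 + 2cos ψ
shows peaks at 1 + 2cos(2πk/n), k = 0..n-1, and the rotation axes of the
S_ij concentrate on the symmetry axes.  Detected (or known) groups can be
fed back to fold inconsistent relative poses onto the identity branch
(symmetry promotion) and to scramble poses during bootstrapping (hotspot
mitigation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial.transform import Rotation
from scipy.stats import gaussian_kde

from smlmfuse.gmm_registration import PairResult, RelativePoseSet
from smlmfuse.lie_averaging import AbsolutePoseSet, ConsistencyRecord, rotation_axis_of
from smlmfuse.particle_store import RigidTransform

MIN_RECORDS_RECOMMENDED = 50


@dataclass
class SymmetryReport:
    """Outcome of fold/axis detection.

    folds: detected folds (best first); fold_scores: candidate -> score
    (lower is better); axes: candidate symmetry axes (unit vectors) with
    weights; trace_histogram: (bin centers, density); peak_positions: trace
    values of the detected KDE peaks.
    """

    folds: list[int]
    fold_scores: dict[int, float]
    axes: list[tuple[np.ndarray, float]] = field(default_factory=list)
    trace_histogram: tuple[np.ndarray, np.ndarray] | None = None
    peak_positions: np.ndarray = field(default_factory=lambda: np.array([]))
    warning: str | None = None


def expected_trace_set(n: int) -> np.ndarray:
    """Trace values {1 + 2cos(2πk/n), k = 0..n-1} of a C_n group, deduplicated.

    C2 -> {3, -1}; C3 -> {3, 0}; C8 -> {3, 1+sqrt2, 1, 1-sqrt2, -1}.
    """
    if n < 1:
        raise ValueError("fold must be >= 1")
    k = np.arange(n)
    vals = 1.0 + 2.0 * np.cos(2 * np.pi * k / n)
    out = []
    for v in vals:
        if not any(np.isclose(v, u, atol=1e-9) for u in out):
            out.append(float(v))
    return np.array(sorted(out, reverse=True))


def _trace_peaks(traces: np.ndarray, bw_floor: float = 0.05,
                 bw_cap: float = 0.12):
    """KDE peak positions of a trace sample.

    The bandwidth is Silverman's rule clamped to [bw_floor, bw_cap]: trace
    distributions of symmetric structures are strongly multimodal with peaks
    as close as ~0.6, where Silverman's unimodal assumption oversmooths and
    merges neighboring peaks.
    """
    traces = np.clip(np.asarray(traces, float), -1.0, 3.0)
    std = traces.std()
    if std < 1e-12:
        return np.array([np.median(traces)]), None
    kde = gaussian_kde(traces)
    bw = float(np.clip(kde.factor * std, bw_floor, bw_cap))
    kde.set_bandwidth(bw / std)
    grid = np.linspace(-1.2, 3.2, 1000)
    dens = kde(grid)
    idx, _ = find_peaks(dens, height=0.05 * dens.max())
    peaks = grid[idx]
    # the identity peak may sit at the clipped boundary 3 without a local max
    if dens[-1] > dens[-2] or (len(peaks) == 0 or peaks.max() < 2.7):
        if dens[np.searchsorted(grid, 2.95)] > 0.05 * dens.max():
            peaks = np.append(peaks, 3.0)
    return np.sort(peaks), (grid, dens)


def _fold_score(peaks: np.ndarray, n: int) -> float:
    """Symmetric mismatch between detected peaks and the expected C_n trace set.

    Combines the distance from every expected value to its nearest detected
    peak (coverage of the group; a missing expected peak is strong evidence
    against the fold, so this term is weighted double) and from every
    detected peak to its nearest expected value (no unexplained peaks);
    lower is better.
    """
    expected = expected_trace_set(n)
    d_exp = np.array([np.abs(peaks - e).min() for e in expected]).mean()
    d_det = np.array([np.abs(expected - p).min() for p in peaks]).mean()
    return float(2.0 * d_exp + d_det)


def detect_fold(records: list[ConsistencyRecord] | np.ndarray,
                candidate_folds: range = range(2, 13),
                match_tol: float = 0.15) -> SymmetryReport:
    """Detect rotational symmetry folds from consistency traces.

    Accepts ConsistencyRecords or a raw array of traces.  Peaks of the trace
    KDE are matched against the expected sets of each candidate fold; folds
    are selected greedily until all detected peaks are explained, so compound
    groups (e.g. the tetrahedron's union of C2 and C3 peaks) are reported as
    multiple folds.  An empty fold list means no symmetry beyond identity was
    found.
    """
    if len(records) and isinstance(records[0], ConsistencyRecord):
        traces = np.array([r.trace for r in records])
        axes = [r.axis for r in records if r.axis is not None]
    else:
        traces = np.asarray(records, dtype=float)
        axes = []
    warning = None
    if len(traces) < MIN_RECORDS_RECOMMENDED:
        warning = (f"only {len(traces)} records; at least "
                   f"{MIN_RECORDS_RECOMMENDED} are recommended for reliable detection")
    peaks, hist = _trace_peaks(traces)
    scores = {n: _fold_score(peaks, n) for n in candidate_folds}
    non_identity = peaks[peaks < 3.0 - match_tol]
    folds: list[int] = []
    if len(non_identity) > 0:
        unexplained = list(non_identity)
        for n in sorted(scores, key=scores.get):
            if not unexplained:
                break
            expected = expected_trace_set(n)
            explains = [p for p in unexplained if np.abs(expected - p).min() <= match_tol]
            if explains:
                folds.append(n)
                unexplained = [p for p in unexplained if p not in explains]
    axis_peaks = axis_density(axes)[1] if axes else []
    return SymmetryReport(folds=folds, fold_scores=scores, axes=axis_peaks,
                          trace_histogram=hist, peak_positions=peaks, warning=warning)


def rotation_axis(S: np.ndarray) -> np.ndarray | None:
    """Unit rotation axis of a consistency matrix from its antisymmetric part;
    None when indeterminate (identity); half turns fall back to the +1
    eigenvector."""
    return rotation_axis_of(np.asarray(S, float))


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta), np.cos(phi)])


def axis_density(axes: list[np.ndarray] | np.ndarray, grid_n: int = 1000,
                 concentrations: tuple[float, ...] = (20.0, 50.0, 100.0),
                 min_separation_deg: float = 20.0,
                 rel_threshold: float = 0.3):
    """Antipodally symmetrized spherical kernel density of rotation axes.

    Axes u and -u are identified (a rotation axis has no sign).  The density
    uses a Watson-type kernel exp(kappa (u.x)^2) whose concentration is
    chosen from a small ladder by leave-one-out likelihood.  Returns
    ``(density_map, maxima)`` where density_map is (grid points, densities)
    and maxima is a list of (unit axis, weight) sorted by weight.
    """
    axes = np.atleast_2d(np.asarray(axes, dtype=float))
    if axes.size == 0:
        raise ValueError("need at least one axis")
    axes = axes / np.linalg.norm(axes, axis=1, keepdims=True)
    # concentration selection by leave-one-out log likelihood
    cos2 = (axes @ axes.T) ** 2
    best_kappa, best_ll = concentrations[0], -np.inf
    for kappa in concentrations:
        K = np.exp(kappa * (cos2 - 1.0))
        np.fill_diagonal(K, 0.0)
        ll = np.log(K.sum(axis=1) + 1e-300).sum()
        if ll > best_ll:
            best_ll, best_kappa = ll, kappa
    grid = _fibonacci_sphere(grid_n)
    dens = np.exp(best_kappa * ((grid @ axes.T) ** 2 - 1.0)).sum(axis=1)
    # greedy maxima: highest-density grid points separated by a minimum
    # angle, each refined to the principal axis of its supporting points
    order = np.argsort(dens)[::-1]
    maxima: list[tuple[np.ndarray, float]] = []
    cos_sep = np.cos(np.deg2rad(min_separation_deg))
    for idx in order:
        if dens[idx] < rel_threshold * dens[order[0]]:
            break
        u = grid[idx]
        if all(abs(u @ v) < cos_sep for v, _ in maxima):
            near = axes[np.abs(axes @ u) > cos_sep]
            if len(near):  # Watson MLE: principal eigenvector of the scatter
                _, vecs = np.linalg.eigh(near.T @ near)
                u = vecs[:, -1]
            maxima.append((u, float(dens[idx])))
    return (grid, dens), maxima


def common_frame_axis(records: list[ConsistencyRecord], poses) -> np.ndarray | None:
    """Symmetry axis expressed in the common (template) frame.

    A symmetry-branch mismatch gives S_ij = R̂_j G R̂_j^{-1} with G the group
    rotation in the common frame, so back-rotating each record's axis by the
    second particle's pose rotation maps it onto the common-frame symmetry
    axis exactly; the density maximum of these back-rotated axes is returned
    (None when no record has a well-defined axis).
    """
    axes = [poses[r.j].rotation.T @ r.axis for r in records if r.axis is not None]
    if not axes:
        return None
    _, maxima = axis_density(np.asarray(axes))
    return maxima[0][0] if maxima else None


def group_rotations(n: int, axis: np.ndarray) -> list[np.ndarray]:
    """Rotation matrices of the cyclic group C_n about the given axis."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    return [Rotation.from_rotvec(2 * np.pi * k / n * axis).as_matrix() for k in range(n)]


def _group_in_particle_frame(gens: list[np.ndarray], pose: RigidTransform,
                             center: np.ndarray) -> list[RigidTransform]:
    """Symmetry-group elements expressed in one particle's frame.

    A group rotation g about an axis through ``center`` of the common frame
    becomes M_i ∘ G_c ∘ M_i^{-1} in particle i's frame, where M_i is the
    particle's pose.
    """
    out = []
    for g in gens:
        G = RigidTransform(g, center - g @ center)
        out.append(pose @ G @ pose.inverse())
    return out


def fold_relative_by_symmetry(rel: RelativePoseSet,
                              records: list[ConsistencyRecord],
                              group: tuple[int, np.ndarray],
                              poses=None,
                              center: np.ndarray | None = None) -> RelativePoseSet:
    """Symmetry promotion: fold each measured relative pose onto the identity
    branch of the symmetry group.

    For each pair the group element S̄_k closest to S_ij is divided out, so
    registrations that landed on another symmetry branch become consistent
    (trace near 3) and survive pruning; the kept-pair count can only grow.
    When current pose estimates are supplied, the group elements are
    conjugated into each particle's frame (about an axis through ``center``
    of the common frame) so translations are corrected as well; otherwise
    the correction acts on rotations about the origin.
    """
    n, axis = group
    gens = group_rotations(n, axis)
    c = np.zeros(3) if center is None else np.asarray(center, float)
    by_pair = {(r.i, r.j): r for r in records}
    out = RelativePoseSet(n_particles=rel.n_particles)
    for res in rel.pairs(kept_only=False):
        rec = by_pair.get((res.i, res.j))
        if rec is None:
            out.add(res)
            out.mask[(res.i, res.j)] = rel.mask[(res.i, res.j)]
            continue
        T = res.transform
        if poses is not None:
            candidates = [T @ G for G in
                          _group_in_particle_frame(gens, poses[res.i], c)]
            Rhat = (poses[res.j] @ poses[res.i].inverse()).rotation
            traces = [np.trace(cand.rotation @ Rhat.T) for cand in candidates]
            corrected = candidates[int(np.argmax(traces))]
        else:
            traces = [np.trace(g.T @ rec.S) for g in gens]
            g = gens[int(np.argmax(traces))]
            corrected = RigidTransform(g.T @ T.rotation, g.T @ T.translation)
        out.add(PairResult(i=res.i, j=res.j, transform=corrected,
                           score=res.score, n_starts=res.n_starts,
                           converged=res.converged))
    return out


def scramble_symmetric_poses(poses: AbsolutePoseSet, group: tuple[int, np.ndarray],
                             rng: np.random.Generator,
                             center: np.ndarray | None = None) -> AbsolutePoseSet:
    """Compose each pose with a random symmetry-group rotation (hotspot fix).

    Adding uniform multiples of 2π/n about the symmetry axis to the alignment
    of each particle balances the localization azimuths over the n symmetric
    sectors across bootstrap iterations while leaving the site set invariant.
    ``center`` anchors the rotation axis in the common frame (default:
    origin).
    """
    n, axis = group
    if n <= 1:
        return poses
    c = np.zeros(3) if center is None else np.asarray(center, float)
    gens = group_rotations(n, axis)
    ks = rng.integers(0, n, size=len(poses))
    new = [poses[i] @ RigidTransform(gens[k], c - gens[k] @ c) for i, k in enumerate(ks)]
    return AbsolutePoseSet(new, reference=poses.reference)
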
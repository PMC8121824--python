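"""Data-driven template construction and bootstrap pose refinement.

The super-particle (union of all particles aligned into the common frame) is
the method's template; each bootstrap round re-registers every particle to a
density-resampled version of it, optionally scrambling poses with random
symmetry-group rotations first to avoid the hotspot artifact on symmetric,
under-labeled structures.
"""

from __future__ import annotations

import logging

import numpy as np

from smlmfuse.gmm_registration import (
    RigidTransform,
    bhattacharyya_cost,
    local_rotation_grid,
    register_pair,
    sample_so3,
    select_scale,
)
from smlmfuse.lie_averaging import AbsolutePoseSet
from smlmfuse.particle_store import LocalizationCloud, ParticleSet, apply_transform
from smlmfuse.symmetry import group_rotations, scramble_symmetric_poses

logger = logging.getLogger(__name__)


def build_superparticle(ps: ParticleSet, poses: AbsolutePoseSet) -> LocalizationCloud:
    """Fuse all particles into one cloud in the common frame.

    Each particle is aligned by the inverse of its pose (the pose maps the
    common frame onto the particle).  The result concatenates every
    localization with its rotated uncertainty axes; the total count is
    conserved.
    """
    if len(ps) != len(poses):
        raise ValueError("particle count and pose count differ")
    coords, slat, sax, sites, orients = [], [], [], [], []
    have_sites = all(p.site_id is not None for p in ps)
    for p, M in zip(ps, poses.poses):
        aligned = apply_transform(p, M.inverse())
        coords.append(aligned.coords)
        slat.append(aligned.sigma_lat)
        sax.append(aligned.sigma_ax)
        if have_sites:
            sites.append(aligned.site_id)
        o = aligned.orientation
        orients.append(np.broadcast_to(o, (len(aligned), 3, 3)) if o.ndim == 2 else o)
    return LocalizationCloud(
        coords=np.vstack(coords),
        sigma_lat=np.concatenate(slat),
        sigma_ax=np.concatenate(sax),
        site_id=np.concatenate(sites) if have_sites else None,
        orientation=np.vstack(orients).reshape(-1, 3, 3),
    )


def density_resample(sp: LocalizationCloud, target_n: int,
                     rng: np.random.Generator,
                     mode: str = "uniform") -> LocalizationCloud:
    """Random subsample of ``target_n`` localizations without replacement.

    ``mode="uniform"`` draws uniformly; ``mode="density_equalizing"`` weights
    points by their inverse local density (5th-nearest-neighbor volume) so
    over-represented regions are thinned harder.
    """
    n = len(sp)
    if target_n > n:
        raise ValueError(f"target_n={target_n} exceeds cloud size {n}")
    if mode == "uniform":
        idx = rng.choice(n, size=target_n, replace=False)
    elif mode == "density_equalizing":
        from scipy.spatial import cKDTree

        k = min(6, n)
        d, _ = cKDTree(sp.coords).query(sp.coords, k=k)
        w = d[:, -1] ** 3 + 1e-12
        idx = rng.choice(n, size=target_n, replace=False, p=w / w.sum())
    else:
        raise ValueError(f"unknown resampling mode {mode!r}")
    orient = sp.orientation if sp.orientation.ndim == 2 else sp.orientation[idx]
    return LocalizationCloud(
        coords=sp.coords[idx],
        sigma_lat=sp.sigma_lat[idx],
        sigma_ax=sp.sigma_ax[idx],
        site_id=None if sp.site_id is None else sp.site_id[idx],
        orientation=orient,
    )


def bootstrap(ps: ParticleSet, poses: AbsolutePoseSet, rounds: int = 5,
              group: tuple[int, np.ndarray] | None = None,
              rng: np.random.Generator | None = None,
              resample_target: int = 5000,
              warm_grid_n: int = 32, warm_radius_deg: float = 30.0,
              scale: float | str = "auto",
              resample_mode: str = "uniform",
              try_inverted: bool = True):
    """Refine poses by iterative registration to density-resampled templates.

    Each round scrambles poses with random symmetry rotations when a group is
    supplied (hotspot fix), builds the super-particle, resamples it, and
    re-registers every particle to the template with a warm-started local
    rotation grid (plus all group elements when a group is active).  With
    ``try_inverted`` the warm starts also include half-turns about a fan of
    in-plane axes: against the densely occupied template, the overlap score
    reliably rejects pseudo-mirror ("upside-down") alignments that pairwise
    registration of sparsely labeled particles cannot always resolve, so
    particles stuck on the wrong side get rescued here.  A particle whose
    re-registration fails keeps its previous pose.

    Returns ``(AbsolutePoseSet, LocalizationCloud)``: final poses and the
    final super-particle.
    """
    if not 1 <= rounds <= 10:
        raise ValueError("rounds must be in 1..10")
    if rng is None:
        rng = np.random.default_rng(0)
    local_grid = local_rotation_grid(warm_grid_n, np.deg2rad(warm_radius_deg))
    group_mats = group_rotations(*group) if group is not None else []
    flip_mats = []
    if try_inverted:
        from scipy.spatial.transform import Rotation

        for beta in np.arange(0.0, np.pi, np.pi / 8):
            ax = np.array([np.cos(beta), np.sin(beta), 0.0])
            flip_mats.append(Rotation.from_rotvec(np.pi * ax).as_matrix())

    for _ in range(rounds):
        if group is not None:
            center = build_superparticle(ps, poses).centroid()
            poses = scramble_symmetric_poses(poses, group, rng, center=center)
        sp = build_superparticle(ps, poses)
        target = min(resample_target, len(sp))
        template = density_resample(sp, target, rng, mode=resample_mode)
        poses = realign_to_template(ps, poses, template, local_grid=local_grid,
                                    group_mats=group_mats, flip_mats=flip_mats,
                                    scale=scale)
    return poses, build_superparticle(ps, poses)


def rotation_angle_between(T1: RigidTransform, T2: RigidTransform) -> float:
    """Geodesic angle (degrees) between the rotation parts of two transforms."""
    tr = np.trace(T1.rotation @ T2.rotation.T)
    return float(np.degrees(np.arccos(np.clip((tr - 1) / 2, -1, 1))))


def progressive_alignment(ps: ParticleSet, quality: np.ndarray,
                          rng: np.random.Generator,
                          grid_n: int = 48,
                          resample_target: int = 1200,
                          margin: float = 1.06,
                          early_margin: float = 1.15,
                          early_core_size: int = 8,
                          ambiguity_angle_deg: float = 60.0,
                          max_passes: int = 3,
                          scale: float | str = "auto") -> AbsolutePoseSet:
    """Grow a clean aligned core by registering particles to an expanding
    template, deferring ambiguous ones.

    Pairwise registration of two sparsely labeled particles can be genuinely
    ambiguous (for near-symmetric structures the wrong branch sometimes
    scores best because of labeling fluctuations), but registration against
    a densely occupied template is not.  Particles are therefore processed
    in order of decreasing ``quality``; each is registered to the current
    template with a full rotation grid, and a particle whose best score does
    not beat its best well-separated rival by ``margin`` is deferred to a
    later pass, when the grown template disambiguates it.  While the core is
    still small (fewer than ``early_core_size`` particles) the stricter
    ``early_margin`` applies — a wrong early acceptance poisons the template
    and is self-reinforcing, so only clear-cut particles may build the core.
    Returns poses in the seed particle's frame.
    """
    n = len(ps)
    order = list(np.argsort(-np.asarray(quality, float)))
    seed = order[0]
    poses: list = [None] * n
    poses[seed] = RigidTransform.identity()
    aligned = {seed: ps[seed]}
    grid = sample_so3(grid_n)
    queue = order[1:]

    def accept(i, transform):
        poses[i] = transform.inverse()
        aligned[i] = apply_transform(ps[i], transform)

    for pass_no in range(max_passes):
        last_pass = pass_no == max_passes - 1
        deferred = []
        best_deferred = None  # (margin ratio, particle, transform)
        for i in queue:
            template = build_superparticle(
                ParticleSet([aligned[k] for k in sorted(aligned)]),
                AbsolutePoseSet([RigidTransform.identity()] * len(aligned)))
            if len(template) > resample_target:
                template = density_resample(template, resample_target, rng)
            s = select_scale(ps[i], template) if scale == "auto" else float(scale)
            res, cands = register_pair(ps[i], template, grid, scale=s,
                                       refine_top=6, return_candidates=True)
            rival = None
            for sc, T in cands[1:]:
                if rotation_angle_between(T, res.transform) > ambiguity_angle_deg:
                    rival = sc
                    break
            need = early_margin if len(aligned) < early_core_size else margin
            # an absent rival is not evidence of safety while the core is
            # small: treat it as ambiguous
            ambiguous = (rival is None and len(aligned) < early_core_size) or \
                        (rival is not None and res.score < need * rival)
            if ambiguous and not last_pass:
                ratio = 1.0 if rival is None else res.score / rival
                if best_deferred is None or ratio > best_deferred[0]:
                    best_deferred = (ratio, i, res.transform)
                deferred.append(i)
                continue
            accept(i, res.transform)
        if deferred and len(deferred) == len(queue) and best_deferred is not None:
            # nothing cleared the bar this pass: force the clearest deferred
            # particle in so the core keeps growing
            _, i, T = best_deferred
            accept(i, T)
            deferred.remove(i)
        queue = deferred
        if not queue:
            break
    return AbsolutePoseSet([p if p is not None else RigidTransform.identity()
                            for p in poses])


def similarity_refine(ps: ParticleSet, poses: AbsolutePoseSet,
                      rng: np.random.Generator, rounds: int = 2,
                      grid_n: int = 48, resample_target: int = 800,
                      n_trial: int = 4,
                      scale: float | str = "auto") -> AbsolutePoseSet:
    """Greedy pose refinement driven by total aligned-particle overlap.

    Robust averaging of a near-dihedral structure can converge to two
    internally consistent camps of mutually flipped particles; pairwise
    registration scores cannot arbitrate (the mixed state explains them at
    least as well), but the total Bhattacharyya overlap between *aligned*
    particles can: a particle flipped relative to the majority overlaps the
    majority poorly, and moving it across strictly increases the total.
    Each round therefore re-registers every particle against the template
    of all others and accepts a candidate pose only if the particle's
    summed overlap with the rest improves.  The trial set always includes
    the particle's current pose composed with half turns about a fan of
    in-plane axes (locally polished), so the opposite-orientation
    hypothesis is evaluated even when the multi-start registration misses
    it.  A 50/50 camp split is unstable under this dynamics — any accepted
    move grows one camp and the gain snowballs — so the refinement
    converges to a single-camp solution.
    """
    from scipy.spatial.transform import Rotation as _Rot

    from smlmfuse.gmm_registration import _gmm_register_raw
    from smlmfuse.outlier_removal import similarity_matrix

    n = len(ps)
    if n < 3:
        return poses
    grid = sample_so3(grid_n)
    eye = RigidTransform.identity()
    flip_mats = [_Rot.from_rotvec(np.pi * np.array([np.cos(b), np.sin(b), 0.0])).as_matrix()
                 for b in np.arange(0.0, np.pi, np.pi / 8)]
    poses = AbsolutePoseSet(list(poses.poses), reference=poses.reference)
    aligned = [apply_transform(ps[i], poses[i].inverse()) for i in range(n)]
    mat = similarity_matrix(ps, poses)
    for _ in range(rounds):
        changed = False
        for i in range(n):
            others = [aligned[j] for j in range(n) if j != i]
            template = build_superparticle(
                ParticleSet(others), AbsolutePoseSet([eye] * (n - 1)))
            if len(template) > resample_target:
                template = density_resample(template, resample_target, rng)
            s = select_scale(ps[i], template) if scale == "auto" else float(scale)
            _, cands = register_pair(ps[i], template, grid, scale=s,
                                     refine_top=n_trial, return_candidates=True)
            trials = [T for _, T in cands[:n_trial + 1]]
            # explicit opposite-orientation hypotheses about the aligned
            # particle's centroid, polished at the fine scale
            align = poses[i].inverse()
            c_al = align.apply(ps[i].centroid())[0]
            flip_cands = []
            for F in flip_mats:
                T0 = RigidTransform(F @ align.rotation,
                                    F @ (align.translation - c_al) + c_al)
                T1, cost, _ = _gmm_register_raw(ps[i].coords, template.coords,
                                                s, T0, 30)
                flip_cands.append((cost, T1))
            flip_cands.sort(key=lambda ct: ct[0])
            trials.extend(T for _, T in flip_cands[:2])
            best_row = mat[i].sum()
            best_T = None
            for T in trials:
                cand_cloud = apply_transform(ps[i], T)
                row = np.array([bhattacharyya_cost(cand_cloud, aligned[j], eye)
                                if j != i else 0.0 for j in range(n)])
                if row.sum() > best_row * (1 + 1e-6):
                    best_row, best_T, best_vals = row.sum(), T, row
            if best_T is not None:
                poses.poses[i] = best_T.inverse()
                aligned[i] = apply_transform(ps[i], best_T)
                mat[i, :] = best_vals
                mat[:, i] = best_vals
                changed = True
        if not changed:
            break
    return poses


def realign_to_template(ps: ParticleSet, poses: AbsolutePoseSet,
                        template: LocalizationCloud,
                        local_grid=None, group_mats=(), flip_mats=(),
                        scale: float | str = "auto",
                        coarse_iter: int = 8,
                        refine_top: int = 3) -> AbsolutePoseSet:
    """Re-register every particle to a template, warm-started from its pose.

    Candidate starts are the current alignment perturbed by a local rotation
    grid, by symmetry-group elements and by in-plane half turns, all acting
    about the aligned particle's centroid so the cloud stays in place while
    its orientation is perturbed.  A particle whose re-registration fails
    keeps its previous pose.
    """
    if local_grid is None:
        local_grid = local_rotation_grid(32, np.deg2rad(30.0))
    new_poses = []
    for i, particle in enumerate(ps):
        align = poses[i].inverse()  # particle -> common frame
        c_al = align.apply(particle.centroid())[0]

        def about_centroid(R):
            return RigidTransform(R @ align.rotation,
                                  R @ (align.translation - c_al) + c_al)

        inits = [about_centroid(d.rotation) for d in local_grid.rotations]
        inits += [about_centroid(g) for g in list(group_mats)[1:]]
        inits += [about_centroid(f) for f in flip_mats]
        s = select_scale(particle, template) if scale == "auto" else float(scale)
        try:
            res = register_pair(particle, template, grid=None, scale=s,
                                i=0, j=1, init_transforms=inits,
                                coarse_iter=coarse_iter, refine_top=refine_top)
            new_poses.append(res.transform.inverse())
        except Exception as exc:  # keep previous pose on failure
            logger.warning("template re-registration failed for particle %d: %s", i, exc)
            new_poses.append(poses[i])
    return AbsolutePoseSet(new_poses, reference=poses.reference)
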
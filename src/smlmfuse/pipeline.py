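"""End-to-end fusion pipeline: simulate/load -> all-to-all registration ->
iterated Lie-algebraic averaging -> symmetry detection (and optional
promotion) -> bootstrap refinement -> outlier removal -> evaluation."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from smlmfuse import evaluation
from smlmfuse.gmm_registration import all_to_all, sample_so3
from smlmfuse.lie_averaging import iterate_averaging, l1_average
from smlmfuse.outlier_removal import flag_outliers, particle_scores, similarity_matrix
from smlmfuse.particle_store import ParticleSet
from smlmfuse.simulator import (
    BindingSiteModel,
    SimulationConfig,
    make_building_model,
    make_dodecahedron_model,
    make_npc_model,
    make_ring_square_model,
    simulate_dataset,
)
from smlmfuse.lie_averaging import (
    AbsolutePoseSet,
    consistency,
    recompute_relative,
)
from smlmfuse.symmetry import detect_fold
from smlmfuse.template_bootstrap import (
    bootstrap,
    build_superparticle,
    similarity_refine,
)

logger = logging.getLogger(__name__)

MODEL_FACTORIES = {
    "npc": make_npc_model,
    "dodecahedron": make_dodecahedron_model,
    "building": make_building_model,
    "ring_square": make_ring_square_model,
}


@dataclass
class PipelineConfig:
    """Declarative configuration of a full fusion run.

    Defaults are sized for a workstation-scale run; the simulation fields
    mirror :class:`~smlmfuse.simulator.SimulationConfig`.
    """

    model: str = "npc"
    mode: str = "PAINT"
    dol: float = 0.5
    mean_locs_per_particle: float = 88.0
    sigma_lat_mean: float = 3.0
    axial_factor: float = 3.0
    tilt_range_deg: float | str = 36.0
    n_particles: int = 30
    seed: int = 0

    grid_n: int = 48
    scale: float | str = "auto"
    epsilon: float = 0.5
    averaging_iters: int = 2
    symmetry: str = "auto"          # "auto", "off", or "Cn:<fold>"
    bootstrap_rounds: int = 5
    resample_target: int = 5000
    remove_outliers: bool = True
    outlier_k: float = 3.0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    superparticle: object
    poses: object
    symmetry_report: object
    outlier_mask: np.ndarray | None
    registration_error: float | None
    manifest: dict
    history: list = field(default_factory=list)


def _resolve_symmetry(cfg: PipelineConfig, records) -> tuple[int, np.ndarray] | None:
    """Symmetry group to use downstream: detected (auto) or user-supplied."""
    if cfg.symmetry == "off":
        return None
    if cfg.symmetry.startswith("Cn:") and cfg.symmetry != "Cn:auto":
        fold = int(cfg.symmetry.split(":", 1)[1])
        report = detect_fold(records)
        axis = report.axes[0][0] if report.axes else np.array([0.0, 0.0, 1.0])
        return fold, axis
    report = detect_fold(records)
    if report.folds and report.axes:
        return report.folds[0], report.axes[0][0]
    return None


def _regauge_to_principal_axes(ps: ParticleSet, poses):
    """Re-express all poses so the common frame has the super-particle's
    principal axes on the coordinate axes (symmetry axis on z, centroid at
    the origin); returns the poses unchanged when the moment analysis is
    ambiguous."""
    from smlmfuse.particle_store import RigidTransform

    sp = build_superparticle(ps, poses)
    try:
        A = evaluation.moment_align(sp)
    except ValueError:
        return poses
    Ainv = A.inverse()
    return AbsolutePoseSet([p @ Ainv for p in poses.poses],
                           reference=poses.reference)


def run_pipeline(cfg: PipelineConfig, ps: ParticleSet | None = None,
                 truth: dict | None = None, model: BindingSiteModel | None = None,
                 dry_run: bool = False) -> PipelineResult | dict:
    """Execute the full fusion pipeline under one master seed.

    When ``ps`` is None a dataset is simulated per the config.  Returns a
    :class:`PipelineResult`; with ``dry_run=True`` only the stage plan and
    manifest are returned.
    """
    stages = ["simulate" if ps is None else "load", "all_to_all",
              "iterate_averaging", "detect_symmetry", "bootstrap",
              "outlier_removal" if cfg.remove_outliers else "keep_all",
              "evaluate"]
    manifest = {"config": asdict(cfg), "config_hash": cfg.config_hash(),
                "seed": cfg.seed, "stages": stages}
    if dry_run:
        return manifest

    seedseq = np.random.SeedSequence(cfg.seed)
    ss_sim, ss_boot, ss_fsc = seedseq.spawn(3)
    timings = {}
    t0 = time.perf_counter()

    if ps is None:
        if cfg.model not in MODEL_FACTORIES:
            raise ValueError(f"unknown model {cfg.model!r}")
        model = MODEL_FACTORIES[cfg.model]()
        sim_cfg = SimulationConfig(
            mode=cfg.mode, dol=cfg.dol,
            mean_locs_per_particle=cfg.mean_locs_per_particle,
            sigma_lat_mean=cfg.sigma_lat_mean, axial_factor=cfg.axial_factor,
            tilt_range_deg=cfg.tilt_range_deg, n_particles=cfg.n_particles,
            seed=int(ss_sim.generate_state(1)[0] % (2**31)))
        ps, truth = simulate_dataset(model, sim_cfg)
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    grid = sample_so3(cfg.grid_n)
    rel = all_to_all(ps, grid, scale=cfg.scale)
    timings["all_to_all"] = time.perf_counter() - t0
    logger.info("all-to-all: %d pairs registered in %.1f s",
                len(rel.results), timings["all_to_all"])

    t0 = time.perf_counter()
    poses_avg, history = iterate_averaging(rel, epsilon=cfg.epsilon,
                                           n_iter=cfg.averaging_iters)
    timings["averaging"] = time.perf_counter() - t0
    logger.info("averaging: %d/%d pairs kept", rel.n_kept(), len(rel.results))

    # overlap-driven refinement resolves the coherent pseudo-mirror failure
    # mode of plain averaging on near-dihedral structures (see methods)
    rng_boot = np.random.default_rng(ss_boot)
    t0 = time.perf_counter()
    poses = similarity_refine(ps, poses_avg, rng_boot, grid_n=cfg.grid_n,
                              scale=cfg.scale)
    timings["similarity_refine"] = time.perf_counter() - t0
    logger.info("similarity refinement: %.1f s", timings["similarity_refine"])

    # re-gauge the common frame onto the structure's principal axes, then
    # read the symmetry group off the consistency records
    poses = _regauge_to_principal_axes(ps, poses)
    records = consistency(rel, recompute_relative(poses))
    history.append(records)
    sym_report = detect_fold(records)
    group = _resolve_symmetry(cfg, records)
    if group is not None:
        # express the symmetry axis in the common frame by back-rotating the
        # record axes through the poses (the raw axis density lives in the
        # per-particle frames)
        from smlmfuse.symmetry import common_frame_axis

        axis = common_frame_axis(records, poses)
        if axis is None:
            axis = np.array([0.0, 0.0, 1.0])
        group = (group[0], axis)
        logger.info("symmetry group: C%d about common-frame axis %s "
                    "(detected folds %s)", group[0], np.round(axis, 3),
                    sym_report.folds)

    t0 = time.perf_counter()
    poses, sp = bootstrap(ps, poses, rounds=cfg.bootstrap_rounds, group=group,
                          rng=rng_boot, resample_target=cfg.resample_target,
                          scale=cfg.scale)
    timings["bootstrap"] = time.perf_counter() - t0

    if group is not None:
        # final gauge: symmetry axis onto z, centroid at the origin
        from smlmfuse.symmetry import common_frame_axis
        from smlmfuse.particle_store import RigidTransform
        from scipy.spatial.transform import Rotation

        records_final = consistency(rel, recompute_relative(poses))
        axis = common_frame_axis(records_final, poses.poses)
        if axis is not None:
            if axis[2] < 0:
                axis = -axis
            rotvec = np.cross(axis, [0.0, 0.0, 1.0])
            norm = np.linalg.norm(rotvec)
            ang = np.arcsin(np.clip(norm, -1, 1)) if axis[2] >= 0 else np.pi
            R = (Rotation.from_rotvec(rotvec / norm * ang).as_matrix()
                 if norm > 1e-12 else np.eye(3))
            c = sp.centroid()
            G = RigidTransform(R, -R @ c)
            poses = AbsolutePoseSet([p @ G.inverse() for p in poses.poses],
                                    reference=poses.reference)
            sp = build_superparticle(ps, poses)

    outlier_mask = None
    if cfg.remove_outliers and len(ps) >= 5:
        mat = similarity_matrix(ps, poses)
        scores = particle_scores(mat)
        outlier_mask = flag_outliers(scores, k=cfg.outlier_k)
        if outlier_mask.any():
            logger.info("flagged %d/%d particles as outliers",
                        int(outlier_mask.sum()), len(ps))
            keep = ~outlier_mask
            ps_kept = ParticleSet([p for p, k in zip(ps, keep) if k], ps.metadata)
            poses_kept = AbsolutePoseSet([p for p, k in zip(poses.poses, keep) if k])
            sp = build_superparticle(ps_kept, poses_kept)

    err = None
    if truth is not None and model is not None:
        idx = range(len(ps)) if outlier_mask is None else np.flatnonzero(~outlier_mask)
        sets = evaluation.aligned_ground_truth_sites(
            model.sites, [truth["poses"][i] for i in idx],
            AbsolutePoseSet([poses.poses[i] for i in idx]))
        err = evaluation.registration_error(
            sets, mode=model.correspondence_mode, ring_size=model.ring_size)
        logger.info("ground-truth registration error: %.2f nm", err)

    manifest["timings_s"] = {k: round(v, 2) for k, v in timings.items()}
    manifest["n_pairs_kept"] = rel.n_kept()
    return PipelineResult(superparticle=sp, poses=poses, symmetry_report=sym_report,
                          outlier_mask=outlier_mask, registration_error=err,
                          manifest=manifest, history=history)
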
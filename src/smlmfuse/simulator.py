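"""Synthetic SMLM particle generation from ground-truth binding-site models.

Implements the benchmark structures used throughout: the Nup107 nuclear pore
complex model (2 x 16 sites on two 8-fold rings), a regular dodecahedron, a
box-frame "building", and an asymmetric "ring-square".  Particles are drawn
from a site model by (a) Bernoulli labeling of each site with probability DOL,
(b) PAINT (Poisson) or STORM (geometric blinks x clustered localizations)
localization counts, (c) anisotropic Gaussian localization noise, and (d) a
random rigid pose (uniform azimuth, bounded tilt, small translation jitter).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from smlmfuse.particle_store import LocalizationCloud, ParticleSet, RigidTransform

GOLDEN_RATIO = (1 + np.sqrt(5)) / 2


@dataclass
class BindingSiteModel:
    """Ground-truth binding-site positions with optional symmetry metadata.

    Attributes
    ----------
    sites : (K, 3) ndarray
        Site positions in nm, centered on the origin.
    name : str
    symmetry_meta : list of (fold, axis) tuples or None
        Known rotational symmetry generators.
    correspondence_mode : {"cyclic", "none"}
        How the registration-error metric matches sites between particles.
    ring_size : int or None
        For cyclic mode with several stacked rings: number of sites per ring
        (sites are ordered ring-by-ring, each ring by azimuth).
    """

    sites: np.ndarray
    name: str = "model"
    symmetry_meta: list | None = None
    correspondence_mode: str = "none"
    ring_size: int | None = None

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=float)
        if self.sites.ndim != 2 or self.sites.shape[1] != 3 or len(self.sites) < 3:
            raise ValueError("sites must be a K x 3 array with K >= 3")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def diameter(self) -> float:
        return float(pdist(self.sites).max())


@dataclass
class SimulationConfig:
    """Study conditions for particle simulation.

    mode : "PAINT" or "STORM" switching kinetics.
    dol : degree of labeling, the probability a site carries an active label.
    mean_locs_per_particle : expected total localization count per particle.
    sigma_lat_mean : mean in-plane localization uncertainty (nm).
    axial_factor : sigma_ax / sigma_lat (axial precision is 2-4x worse; default 3).
    sigma_cv : coefficient of variation of the per-localization sigma draw.
    tilt_range_deg : half-range of the pose tilt in degrees, or "random" for a
        uniform rotation over SO(3).
    translation_jitter_nm : half-range of the uniform per-axis pose translation.
    storm_mu_on : mean extra localizations per blink (STORM only).
    """

    mode: str = "PAINT"
    dol: float = 0.5
    mean_locs_per_particle: float = 60.0
    sigma_lat_mean: float = 3.0
    axial_factor: float = 3.0
    sigma_cv: float = 0.3
    tilt_range_deg: float | str = 36.0
    translation_jitter_nm: float = 10.0
    storm_mu_on: float = 0.5
    n_particles: int = 100
    n_datasets: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.dol <= 1:
            raise ValueError("dol must be in (0, 1]")
        if self.sigma_lat_mean <= 0:
            raise ValueError("sigma_lat_mean must be positive")
        if self.axial_factor < 1:
            raise ValueError("axial_factor must be >= 1")
        if self.mode not in ("PAINT", "STORM"):
            raise ValueError("mode must be PAINT or STORM")


def make_npc_model(radius: float = 49.7, height: float = 59.0,
                   azimuthal_shift: float = 13.0,
                   pair_split_deg: float = 12.0,
                   radius_inner: float | None = 42.7) -> BindingSiteModel:
    """Nup107 NPC model: 2 x 16 sites in eight pairs on two 8-fold rings.

    Each ring holds 8 pairs at C8 spacing (45 deg); pair members are
    separated by ``pair_split_deg`` in azimuth and sit on two concentric
    circles (default 49.7 and 42.7 nm), reflecting the stacked inner/outer
    Y-complex arrangement of each NPC ring.  The radial offset also breaks
    the mirror (dihedral) pseudo-symmetry of a two-ring arrangement — with
    all sites on one circle the site set would be exactly dihedral and the
    up/down orientation of a particle would be unrecoverable in principle —
    leaving the pure C8 group.  The lower ring (z = -height/2) is rotated by
    ``azimuthal_shift`` degrees relative to the upper ring (default 13 deg).
    ``radius_inner=None`` puts all sites on one circle (dihedral geometry).
    """
    if radius <= 0 or height <= 0:
        raise ValueError("radius and height must be positive")
    r_in = radius if radius_inner is None else radius_inner
    if r_in <= 0:
        raise ValueError("radius_inner must be positive")
    split = np.deg2rad(pair_split_deg)
    shift = np.deg2rad(azimuthal_shift)
    rings = []
    for z, offset in ((height / 2, 0.0), (-height / 2, shift)):
        centers = np.arange(8) * (2 * np.pi / 8) + offset
        az = np.concatenate([centers - split / 2, centers + split / 2])
        rr = np.concatenate([np.full(8, radius), np.full(8, r_in)])
        order = np.argsort(az)
        az, rr = az[order], rr[order]
        rings.append(np.column_stack([rr * np.cos(az), rr * np.sin(az),
                                      np.full(16, z)]))
    sites = np.vstack(rings)
    sites -= sites.mean(axis=0)
    return BindingSiteModel(sites, name="npc", symmetry_meta=[(8, np.array([0.0, 0.0, 1.0]))],
                            correspondence_mode="cyclic", ring_size=16)


def make_dodecahedron_model(min_site_distance: float = 30.9) -> BindingSiteModel:
    """Regular dodecahedron with 20 vertex sites; the minimum pairwise distance
    (the edge length) is scaled to ``min_site_distance`` nm."""
    if min_site_distance <= 0:
        raise ValueError("min_site_distance must be positive")
    phi = GOLDEN_RATIO
    verts = []
    for sx in (-1, 1):
        for sy in (-1, 1):
            for sz in (-1, 1):
                verts.append((sx, sy, sz))
    for a in (-1 / phi, 1 / phi):
        for b in (-phi, phi):
            verts.append((0.0, a, b))
            verts.append((a, b, 0.0))
            verts.append((b, 0.0, a))
    verts = np.asarray(verts, dtype=float)
    verts *= min_site_distance / pdist(verts).min()
    verts -= verts.mean(axis=0)
    return BindingSiteModel(verts, name="dodecahedron", correspondence_mode="none")


def make_building_model() -> BindingSiteModel:
    """Semi-symmetric "building": 20 sites on a 20 x 100 x 60 nm box frame."""
    xs = np.array([-10.0, 10.0])
    ys = np.linspace(-50.0, 50.0, 5)
    zs = np.array([-30.0, 30.0])
    sites = np.array([(x, y, z) for x in xs for y in ys for z in zs])
    sites -= sites.mean(axis=0)
    return BindingSiteModel(sites, name="building", correspondence_mode="none")


def make_ring_square_model() -> BindingSiteModel:
    """Asymmetric structure: an 8-point square plus an 8-point ring whose
    center is offset from the square's and whose plane is tilted 26.6 deg
    from horizontal, breaking any possible symmetry."""
    # square of side 60 nm in the z = 0 plane: corners + edge midpoints
    s = 30.0
    square = np.array([(-s, -s, 0), (0, -s, 0), (s, -s, 0), (s, 0, 0),
                       (s, s, 0), (0, s, 0), (-s, s, 0), (-s, 0, 0)], dtype=float)
    az = np.arange(8) * (2 * np.pi / 8)
    ring = np.column_stack([40.0 * np.cos(az), 40.0 * np.sin(az), np.zeros(8)])
    tilt = Rotation.from_rotvec(np.deg2rad(26.6) * np.array([1.0, 0.0, 0.0])).as_matrix()
    ring = ring @ tilt.T + np.array([15.0, 10.0, 35.0])
    sites = np.vstack([square, ring])
    sites -= sites.mean(axis=0)
    return BindingSiteModel(sites, name="ring_square", correspondence_mode="none")


def _site_localization_counts(n_labeled: int, n_sites: int, cfg: SimulationConfig,
                              rng: np.random.Generator) -> np.ndarray:
    """Draw per-labeled-site localization counts for PAINT or STORM kinetics.

    Both laws share the same expected total (dol * K * per-site mean); STORM's
    geometric-blink clustering makes its per-site counts over-dispersed
    relative to PAINT's Poisson counts.
    """
    mean_per_site = cfg.mean_locs_per_particle / (cfg.dol * n_sites)
    if cfg.mode == "PAINT":
        return rng.poisson(mean_per_site, size=n_labeled)
    # STORM: blinks per fluorophore ~ Geometric(p_bleach) (support >= 1),
    # localizations per blink ~ 1 + Poisson(mu_on); per-site mean is
    # (1/p) * (1 + mu_on), solved for p to hit the requested mean.
    mu_on = cfg.storm_mu_on
    p = (1.0 + mu_on) / mean_per_site
    if p > 1.0:
        # requested mean below one blink's worth: shrink the blink size instead
        p = 1.0
        mu_on = max(mean_per_site - 1.0, 0.0)
    blinks = rng.geometric(p, size=n_labeled)
    counts = np.array([b + rng.poisson(mu_on * b) for b in blinks])
    return counts


def _random_pose(cfg: SimulationConfig, rng: np.random.Generator) -> RigidTransform:
    if isinstance(cfg.tilt_range_deg, str) and cfg.tilt_range_deg == "random":
        q = rng.standard_normal(4)
        R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
    else:
        azimuth = rng.uniform(0, 2 * np.pi)
        Rz = Rotation.from_rotvec([0, 0, azimuth]).as_matrix()
        tilt = np.deg2rad(rng.uniform(-float(cfg.tilt_range_deg), float(cfg.tilt_range_deg)))
        phi = rng.uniform(0, 2 * np.pi)
        axis = np.array([np.cos(phi), np.sin(phi), 0.0])
        Rt = Rotation.from_rotvec(tilt * axis).as_matrix()
        R = Rt @ Rz
    t = rng.uniform(-cfg.translation_jitter_nm, cfg.translation_jitter_nm, size=3)
    return RigidTransform(R, t)


def simulate_particle(model: BindingSiteModel, cfg: SimulationConfig,
                      rng: np.random.Generator):
    """Simulate one particle.

    Returns ``(cloud, pose, active_mask)``: the localization cloud (possibly
    empty when no site got labeled — callers resample), the ground-truth pose
    mapping model coordinates to the particle frame, and the per-site labeling
    mask.
    """
    active = rng.random(model.n_sites) < cfg.dol
    pose = _random_pose(cfg, rng)
    idx = np.flatnonzero(active)
    if len(idx) == 0:
        return None, pose, active
    counts = _site_localization_counts(len(idx), model.n_sites, cfg, rng)
    keep = counts > 0
    idx, counts = idx[keep], counts[keep]
    if len(idx) == 0:
        return None, pose, active
    site_of_loc = np.repeat(idx, counts)
    n = len(site_of_loc)
    if cfg.sigma_cv > 0:
        shape = 1.0 / cfg.sigma_cv**2
        sigma_lat = rng.gamma(shape, cfg.sigma_lat_mean / shape, size=n)
    else:
        sigma_lat = np.full(n, cfg.sigma_lat_mean)
    sigma_ax = cfg.axial_factor * sigma_lat
    noise = rng.standard_normal((n, 3)) * np.column_stack([sigma_lat, sigma_lat, sigma_ax])
    coords = pose.apply(model.sites[site_of_loc] + noise)
    cloud = LocalizationCloud(coords=coords, sigma_lat=sigma_lat, sigma_ax=sigma_ax,
                              site_id=site_of_loc, orientation=pose.rotation)
    return cloud, pose, active


def simulate_dataset(model: BindingSiteModel, cfg: SimulationConfig,
                     seed: int | None = None):
    """Simulate ``cfg.n_particles`` independent particles.

    Returns ``(ParticleSet, ground_truth)`` where ground_truth is a dict with
    the true poses, per-site active masks and the model.  Empty particles
    (no labeled site, or zero localizations) are resampled.  Deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    particles, poses, actives = [], [], []
    while len(particles) < cfg.n_particles:
        cloud, pose, active = simulate_particle(model, cfg, rng)
        if cloud is None:
            continue
        particles.append(cloud)
        poses.append(pose)
        actives.append(active)
    ps = ParticleSet(particles, metadata={"model": model.name, "mode": cfg.mode,
                                          "dol": cfg.dol, "seed": cfg.seed})
    truth = {"poses": poses, "active": np.array(actives), "model": model}
    return ps, truth
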
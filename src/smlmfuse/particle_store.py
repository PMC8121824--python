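"""Domain types and file I/O for 3D localization data and rigid transforms.

Coordinate convention (used throughout the package): right-handed axes with z
along the optical axis; rigid transforms act on column vectors as x' = Rx + t.
All lengths are in nanometres.

Each localization carries an anisotropic Gaussian uncertainty
diag(sigma_lat^2, sigma_lat^2, sigma_ax^2) expressed in the particle's current
orientation; applying a rigid transform conjugates this covariance by the
rotation.  The covariance is stored lazily as (sigma_lat, sigma_ax,
orientation) and expanded to per-point 3x3 matrices only where a cost function
needs them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

_ORTHO_TOL = 1e-9

CSV_COLUMNS = ["particle_id", "x_nm", "y_nm", "z_nm", "sigma_lat_nm", "sigma_ax_nm"]


class SchemaError(ValueError):
    """A localization table violates the expected schema or invariants."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion of 3D space: an element of SE(3).

    Attributes
    ----------
    rotation : (3, 3) ndarray
        Proper rotation matrix (orthogonal, det = +1).
    translation : (3,) ndarray
        Translation in nm.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {R.shape}")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        from scipy.spatial.transform import Rotation

        return cls(Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix(),
                   np.asarray(translation, float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply x' = Rx + t to an (N, 3) array of points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply `other` first, then `self`)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


@dataclass
class LocalizationCloud:
    """One segmented particle: 3D localizations with anisotropic uncertainties.

    Attributes
    ----------
    coords : (N, 3) ndarray
        Localization coordinates in nm.
    sigma_lat : (N,) ndarray
        Per-localization lateral (in-plane) uncertainty in nm, > 0.
    sigma_ax : (N,) ndarray
        Per-localization axial uncertainty in nm, > 0; typically 2-4x sigma_lat.
    site_id : (N,) int ndarray, optional
        Ground-truth binding-site index per localization (simulation only).
    orientation : (3, 3) or (N, 3, 3) ndarray
        Accumulated rotation of the uncertainty principal axes relative to the
        lab frame in which sigma_lat/sigma_ax are axis-aligned; per-point when
        the cloud merges particles with different orientations.
    """

    coords: np.ndarray
    sigma_lat: np.ndarray
    sigma_ax: np.ndarray
    site_id: np.ndarray | None = None
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        n = len(self.coords)
        self.sigma_lat = np.broadcast_to(np.asarray(self.sigma_lat, float), (n,)).copy()
        self.sigma_ax = np.broadcast_to(np.asarray(self.sigma_ax, float), (n,)).copy()
        if self.coords.shape != (n, 3):
            raise SchemaError(f"coords must be (N, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise SchemaError("coords contain non-finite values")
        if not (np.all(self.sigma_lat > 0) and np.all(self.sigma_ax > 0)):
            raise SchemaError("sigma_lat and sigma_ax must be positive")
        if self.site_id is not None:
            self.site_id = np.asarray(self.site_id, dtype=int)
            if self.site_id.shape != (n,):
                raise SchemaError("site_id length must match coords")
        self.orientation = np.asarray(self.orientation, dtype=float)

    def __len__(self) -> int:
        return len(self.coords)

    def covariances(self) -> np.ndarray:
        """Expand the lazy uncertainty storage to per-point (N, 3, 3) covariances."""
        d = np.zeros((len(self), 3, 3))
        d[:, 0, 0] = self.sigma_lat**2
        d[:, 1, 1] = self.sigma_lat**2
        d[:, 2, 2] = self.sigma_ax**2
        R = self.orientation
        if R.ndim == 2:
            return np.einsum("ab,nbc,dc->nad", R, d, R)
        return np.einsum("nab,nbc,ndc->nad", R, d, R)

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass
class ParticleSet:
    """Ordered collection of particles; indices 0..N-1 are stable identifiers."""

    particles: list[LocalizationCloud]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.particles)

    def __getitem__(self, i: int) -> LocalizationCloud:
        return self.particles[i]

    def __iter__(self):
        return iter(self.particles)

    def total_localizations(self) -> int:
        return sum(len(p) for p in self.particles)


def apply_transform(cloud: LocalizationCloud, T: RigidTransform) -> LocalizationCloud:
    """Rigidly transform a cloud; uncertainty principal axes rotate with R."""
    return LocalizationCloud(
        coords=T.apply(cloud.coords),
        sigma_lat=cloud.sigma_lat.copy(),
        sigma_ax=cloud.sigma_ax.copy(),
        site_id=None if cloud.site_id is None else cloud.site_id.copy(),
        orientation=np.matmul(T.rotation, cloud.orientation),
    )


def _particles_to_frame(ps: ParticleSet) -> pd.DataFrame:
    frames = []
    has_sites = all(p.site_id is not None for p in ps)
    for i, p in enumerate(ps):
        df = pd.DataFrame({
            "particle_id": i,
            "x_nm": p.coords[:, 0],
            "y_nm": p.coords[:, 1],
            "z_nm": p.coords[:, 2],
            "sigma_lat_nm": p.sigma_lat,
            "sigma_ax_nm": p.sigma_ax,
        })
        if has_sites:
            df["site_id"] = p.site_id
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_particles(ps: ParticleSet, path, format: str = "csv") -> None:
    """Write a ParticleSet losslessly to CSV or HDF5 (one group per particle)."""
    if len(ps) == 0:
        raise SchemaError("refusing to write an empty ParticleSet")
    if format == "csv":
        _particles_to_frame(ps).to_csv(path, index=False, float_format="%.17g")
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["units"] = "nm"
            for key, val in ps.metadata.items():
                f.attrs[f"meta_{key}"] = str(val)
            for i, p in enumerate(ps):
                g = f.create_group(f"particle_{i:06d}")
                g.attrs["units"] = "nm"
                g.create_dataset("coords", data=p.coords)
                g.create_dataset("sigma", data=np.column_stack([p.sigma_lat, p.sigma_ax]))
                if p.site_id is not None:
                    g.create_dataset("site_id", data=p.site_id)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_particles(path, format: str = "csv") -> ParticleSet:
    """Read a ParticleSet written by :func:`write_particles` (or compatible tables).

    CSV tables need columns particle_id, x_nm, y_nm, z_nm, sigma_lat_nm,
    sigma_ax_nm and may carry an optional site_id column.  The particle_id
    column partitions rows into particles, ordered by its value.
    """
    if format == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        particles = []
        for pid, sub in df.groupby("particle_id", sort=True):
            if len(sub) == 0:
                raise SchemaError(f"particle {pid} is empty")
            particles.append(LocalizationCloud(
                coords=sub[["x_nm", "y_nm", "z_nm"]].to_numpy(float),
                sigma_lat=sub["sigma_lat_nm"].to_numpy(float),
                sigma_ax=sub["sigma_ax_nm"].to_numpy(float),
                site_id=sub["site_id"].to_numpy(int) if "site_id" in sub.columns else None,
            ))
        if not particles:
            raise SchemaError("file contains no particles")
        return ParticleSet(particles, metadata={"source": str(path)})
    elif format == "hdf5":
        particles = []
        with h5py.File(path, "r") as f:
            for name in sorted(f.keys()):
                g = f[name]
                if "coords" not in g or "sigma" not in g:
                    raise SchemaError(f"group {name} lacks coords/sigma datasets")
                sigma = np.asarray(g["sigma"])
                particles.append(LocalizationCloud(
                    coords=np.asarray(g["coords"]),
                    sigma_lat=sigma[:, 0],
                    sigma_ax=sigma[:, 1],
                    site_id=np.asarray(g["site_id"]) if "site_id" in g else None,
                ))
        if not particles:
            raise SchemaError("file contains no particles")
        return ParticleSet(particles, metadata={"source": str(path)})
    raise ValueError(f"unknown format {format!r}")
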
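import numpy as np
import pytest

from smlmfuse.particle_store import LocalizationCloud, ParticleSet, RigidTransform
from smlmfuse.simulator import make_npc_model, make_ring_square_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def npc_model():
    return make_npc_model()


@pytest.fixture
def asymmetric_cloud(rng):
    """A 60-localization cloud over the asymmetric ring-square sites."""
    sites = make_ring_square_model().sites
    idx = rng.integers(0, len(sites), size=60)
    coords = sites[idx] + rng.normal(0, 1.5, (60, 3))
    return LocalizationCloud(coords, sigma_lat=2.0, sigma_ax=6.0, site_id=idx)


@pytest.fixture
def small_particle_set(rng):
    particles = []
    for _ in range(3):
        coords = rng.normal(0, 20, (12, 3))
        particles.append(LocalizationCloud(coords, sigma_lat=3.0, sigma_ax=9.0))
    return ParticleSet(particles)


def random_rigid_transform(rng, translation_scale=10.0) -> RigidTransform:
    from scipy.spatial.transform import Rotation

    q = rng.standard_normal(4)
    return RigidTransform(Rotation.from_quat(q / np.linalg.norm(q)).as_matrix(),
                          rng.uniform(-translation_scale, translation_scale, 3))
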
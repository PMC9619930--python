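import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from confpot import ConformerRecord

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20231019)


def random_record(rng, n_atoms=None, mol="m", conf="0"):
    """A random (not chemically meaningful) C/H/O point cloud, min-separated
    so that angle geometry is well conditioned."""
    n = n_atoms or int(rng.integers(3, 9))
    while True:
        coords = rng.uniform(-3.0, 3.0, size=(n, 3))
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() > 0.8:
            break
    elements = tuple(rng.choice(["C", "H", "O"], size=n))
    return ConformerRecord(mol, conf, elements, coords, provenance="random")


@pytest.fixture
def record_factory(rng):
    def make(n_atoms=None, mol="m", conf="0"):
        return random_record(rng, n_atoms, mol, conf)

    return make


def rigid_transform(rng, coords):
    """Random proper or improper rotation plus translation."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if rng.random() < 0.5:
        q[:, 0] *= -1.0  # allow reflections
    return coords @ q.T + rng.uniform(-10, 10, size=3)
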
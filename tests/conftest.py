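import numpy as np
import pytest

from cranialink.geometry import MechanismConfig
from cranialink.synth import SynthesisParams, default_geometry, generate_geometry


@pytest.fixture(scope="session")
def config():
    return MechanismConfig()


@pytest.fixture(scope="session")
def default_geom():
    return default_geometry()


@pytest.fixture(scope="session")
def random_geoms(config):
    """A handful of seeded random geometries for property tests."""
    return [generate_geometry(SynthesisParams(seed), config) for seed in range(5)]


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random rotation matrix from a random rotation vector."""
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
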
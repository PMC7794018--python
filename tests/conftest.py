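import numpy as np
import pytest

from periradiomics.datatypes import CTVolume, ROIMask
from periradiomics.features import FeatureManifest
from periradiomics.synthetic import SimulationConfig, generate_phantom


def make_sphere_mask(radius_mm, spacing=(1.0, 1.0, 1.0), shape=None, role="intratumoral"):
    """Digital sphere: voxels whose centre lies within radius_mm of the centre."""
    spacing = np.asarray(spacing, dtype=float)
    if shape is None:
        shape = tuple(int(2 * np.ceil(radius_mm / s) + 7) for s in spacing)
    centre = (np.asarray(shape) - 1) / 2.0
    idx = np.indices(shape, dtype=float)
    r = np.sqrt(sum(((idx[a] - centre[a]) * spacing[a]) ** 2 for a in range(3)))
    return ROIMask(r <= radius_mm, tuple(spacing), role)


@pytest.fixture(scope="session")
def manifest():
    return FeatureManifest()


@pytest.fixture(scope="session")
def phantom_pair():
    """One aggressive-class phantom (volume, tumor mask) at default settings."""
    cfg = SimulationConfig()
    return generate_phantom(cfg, "aggressive", 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
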
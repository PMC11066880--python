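import numpy as np
import pytest

from subtomo import correlation, simulator, wedge


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom24():
    """Asymmetric blob-cluster phantom, 24-voxel box."""
    return simulator.make_phantom("blob_cluster", 24, seed=5)


@pytest.fixture(scope="session")
def phantom32():
    return simulator.make_phantom("blob_cluster", 32, seed=5)


@pytest.fixture(scope="session")
def wedge_list():
    """Typical acquisition: -60..60 deg in 3 deg steps, dose-symmetric."""
    return wedge.make_wedge_list()


@pytest.fixture(scope="session")
def amp_wedge32(wedge_list):
    return wedge.amplitude_wedge((0.0, 0.0, 0.0), wedge_list, 32)


@pytest.fixture(scope="session")
def mask24():
    return correlation.spherical_mask(24, 9, 2)


@pytest.fixture(scope="session")
def mask32():
    return correlation.spherical_mask(32, 12, 2)
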
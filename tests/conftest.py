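import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from postarray import ArrayGeometry, default_panel, simulate_scan, uniform_truth


@pytest.fixture
def geometry():
    """The reference device: 28x28 wells, 5 posts/well, 5 um/pixel."""
    return ArrayGeometry()


@pytest.fixture
def small_geometry():
    """A 6x6 device for fast tests; same well/post dimensions."""
    return ArrayGeometry(n_rows=6, n_cols=6)


@pytest.fixture
def panel():
    return default_panel()


# per-post true intensities for the default 5-plex panel, all wells identical
PANEL_LEVELS = {0: 500.0, 1: 400.0, 2: 300.0, 3: 2000.0, 4: 130.0}


@pytest.fixture
def small_scan(small_geometry):
    """Noiseless scan of the 6x6 device with known per-post intensities."""
    truth = uniform_truth(small_geometry, PANEL_LEVELS, background=100.0, seed=7)
    image, truth = simulate_scan(small_geometry, truth)
    return image, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20241)
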
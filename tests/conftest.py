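import numpy as np
import pytest

from glvchoice.movie import AcquisitionGeometry
from glvchoice import synthgen


@pytest.fixture
def small_geometry() -> AcquisitionGeometry:
    """Reduced frame size (same timing) for fast unit tests."""
    return AcquisitionGeometry(height=64, width=80)


@pytest.fixture
def small_truth(small_geometry) -> synthgen.GroundTruthMovie:
    """One centered glomerulus on a small frame; no corruptions."""
    g = synthgen.Glomerulus(32, 40, sigma_um=25.0,
                            amplitude_dff={"stim": 0.05})
    return synthgen.GroundTruthMovie(
        glomeruli=[g], baseline_level=400.0, camera_offset=0.0,
        bleach_fraction=0.0, noise_sd=0.0, decay_tau_s=1.0, seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
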
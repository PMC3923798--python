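import numpy as np
import pytest
from hypothesis import settings

from eggscan import phantom as ph

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest geometry whose egg still holds a 1000-px ROI."""
    return ph.tiny(seed=123)


@pytest.fixture(scope="session")
def noise_free_config():
    """Deterministic smooth phantom: no speckle, sensor noise or jitter."""
    return ph.PhantomConfig().noise_free()


@pytest.fixture(scope="session")
def calibrated_d4():
    """One calibrated developed-egg cube at day 4 with its ground truth."""
    from eggscan.envi import calibrate

    cfg = ph.PhantomConfig(seed=5)
    cube, truth = ph.generate_phantom_cube(cfg, "D", 4, 4242)
    refs = ph.generate_references(cfg)
    return calibrate(cube, refs), truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
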
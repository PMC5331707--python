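import numpy as np
import pytest

from lvtorsion.phantom import PhantomConfig, RespiratoryConfig, plan_slices


@pytest.fixture(scope="session")
def default_cfg():
    return PhantomConfig()


@pytest.fixture(scope="session")
def noiseless_cfg():
    return PhantomConfig(phase_noise_sd=0.0)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small, fast phantom used for replicate-heavy tests."""
    return PhantomConfig(grid_size=24, endo_radius_ed=12.0, epi_radius_ed=20.0,
                         n_frames=8)


@pytest.fixture(scope="session")
def resp_default():
    return RespiratoryConfig()


@pytest.fixture(scope="session")
def default_plan(default_cfg):
    return plan_slices(default_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
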
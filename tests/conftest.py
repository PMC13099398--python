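import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from lrtcmr.phantom import PhantomConfig, build_phantom
from lrtcmr.schedule import SequenceParams, build_schedule


@pytest.fixture(scope="session")
def small_phantom():
    """48x48x4 phantom with default injury substructure."""
    cfg = PhantomConfig(grid=(48, 48, 4), voxel_mm=(270 / 48, 270 / 48, 6.0))
    return build_phantom(cfg, seed=0)


@pytest.fixture(scope="session")
def default_params():
    return SequenceParams()


@pytest.fixture(scope="session")
def small_params():
    return SequenceParams(n_ky=48, n_kz=4, duration_s=60.0)


@pytest.fixture(scope="session")
def small_schedule(small_params):
    return build_schedule(small_params, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
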
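import numpy as np
import pytest

from ofcreach import make_task, run_sweep
from ofcreach.lqr import build_point_mass_model


@pytest.fixture(scope="session")
def model():
    return build_point_mass_model()


@pytest.fixture(scope="session")
def profiles():
    """Free-movement intensity sweeps of the three tasks (deterministic)."""
    return {name: run_sweep(make_task(name)) for name in ("stop", "hit", "long_stop")}


@pytest.fixture(scope="session")
def channel_profiles():
    return {name: run_sweep(make_task(name), mode="channel") for name in ("stop", "hit", "long_stop")}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
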
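import numpy as np
import pytest

from popcode import io as pio
from popcode import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_recording():
    """Two units, five spikes each, 100 s session."""
    return pio.Recording(
        mouse_id="mA", day_id="d1", probe_id="p1", area="flM1",
        hemisphere="right", duration=100.0,
        units=[
            pio.SpikeTrain("u000", np.array([1.0, 5.0, 20.0, 55.5, 99.0])),
            pio.SpikeTrain("u001", np.array([0.5, 2.0, 3.0, 80.0, 90.0]),
                           unit_class="multi", channel=7),
        ],
    )


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Small noiseless session reused by ethogram/peth tests."""
    return synth.make_scenario(
        "flM1_like", seed=2,
        behavior={"cycles_per_condition": 6},
        population={"n_units": 12},
    )


def poisson_train(rate_hz: float, duration: float, rng) -> np.ndarray:
    """Homogeneous Poisson spike train helper for null simulations."""
    n = rng.poisson(rate_hz * duration)
    return np.sort(rng.uniform(0.0, duration, n))
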
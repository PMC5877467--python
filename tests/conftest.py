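import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pactkit as pk

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def hour_timeline() -> pk.BehaviorTimeline:
    """One simulated hour with a couple of smoking sessions."""
    return pk.simulate_behavior(pk.SimConfig(seed=11, duration_s=3600.0))


@pytest.fixture(scope="session")
def quiet_timeline() -> pk.BehaviorTimeline:
    """Ten smoke-free minutes (no cigarettes, no walking)."""
    cfg = pk.SimConfig(
        seed=5,
        duration_s=600.0,
        cigarettes_per_day=0.0,
        walk_fraction=0.0,
        spurious_press_rate_per_day=0.0,
    )
    return pk.simulate_behavior(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


def make_stream(data, rate_hz=100.0, channels=None, units=None, start=0.0):
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    n_ch = data.shape[1]
    return pk.SensorStream(
        device_id="test",
        channels=channels or [f"ch{i}" for i in range(n_ch)],
        units=units or ["mV"] * n_ch,
        sampling_rate_hz=rate_hz,
        start_time_s=start,
        data=data,
    )
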
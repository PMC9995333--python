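import dataclasses

import numpy as np
import pytest

from floatpump.constants import Constants
from floatpump.synthetic import MissionConfig, TrapConfig, generate_mission


@pytest.fixture(scope="session")
def constants():
    return Constants()


@pytest.fixture(scope="session")
def full_mission():
    """One full-length mission under the default study conditions."""
    return generate_mission(MissionConfig(), seed=11)


@pytest.fixture(scope="session")
def short_mission():
    """A 120-day mission for cheaper end-to-end checks."""
    cfg = dataclasses.replace(MissionConfig(), duration_days=120.0,
                              esp_events=(MissionConfig().esp_events[0],))
    return generate_mission(cfg, seed=7)


@pytest.fixture(scope="session")
def quiet_trap_config():
    """Noise-free trap model (no measurement noise, no optical spikes)."""
    return dataclasses.replace(
        MissionConfig(),
        trap=dataclasses.replace(TrapConfig(), noise_sd=0.0,
                                 optical_spike_rate_per_day=0.0),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
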
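import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from looselayer import mab_panel_preset, simulate_qcmd


@pytest.fixture(scope="session")
def noiseless_trastuzumab():
    scenario, schedule = mab_panel_preset("trastuzumab")
    scenario = scenario.replace(noise_sd_f=0.0, noise_sd_d=0.0)
    return simulate_qcmd(scenario, schedule), scenario, schedule


@pytest.fixture(scope="session")
def noisy_trastuzumab():
    scenario, schedule = mab_panel_preset("trastuzumab", seed=42)
    return simulate_qcmd(scenario, schedule), scenario, schedule


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)
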
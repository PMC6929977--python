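import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from sersmeth.spectra import PreprocessConfig, Spectrum
from sersmeth.synthetic import SimulationConfig


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def clean_config(sim_config) -> SimulationConfig:
    return sim_config.noiseless()


@pytest.fixture(scope="session")
def prep_off() -> PreprocessConfig:
    """Preprocessing chain with every step disabled (identity)."""
    return PreprocessConfig(smooth=False, baseline=False, normalize=False)


@pytest.fixture()
def ramp_spectrum() -> Spectrum:
    w = np.linspace(600.0, 1700.0, 221)
    return Spectrum(w, 0.5 + 0.002 * (w - 600.0), {"sample": "ramp"})
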
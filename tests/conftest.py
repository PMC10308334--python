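import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from evsense.synthetic_data import GeneratorConfig

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def noiseless_config() -> GeneratorConfig:
    """Generator with every noise source switched off."""
    return GeneratorConfig(
        seed=20230612,
        spr_noise_sd_frac=0.0,
        qcmd_freq_noise_sd=0.0,
        qcmd_diss_noise_sd=0.0,
        panel_conc_cv=0.0,
        panel_reference_cv=0.0,
    )


@pytest.fixture
def default_config() -> GeneratorConfig:
    return GeneratorConfig(seed=20230612)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230612)
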
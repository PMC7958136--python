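import numpy as np
import pytest
from hypothesis import HealthCheck, settings

# one deterministic hypothesis profile for the whole suite
settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

import protonleak as pl


@pytest.fixture
def quiet_cfg():
    """Generator config with every noise source switched off."""
    return pl.GeneratorConfig(
        seed=0,
        noise_sd_current=0.0,
        noise_cv_conductance=0.0,
        correlation_noise_scale=0.0,
        correlation_noise_floor=0.0,
    )


@pytest.fixture
def wide_grid_cfg():
    """Quiet config with a dense voltage grid out to +/-190 mV."""
    return pl.GeneratorConfig(
        seed=0,
        noise_sd_current=0.0,
        voltage_grid=np.arange(-190.0, 191.0, 10.0),
    )
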
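import numpy as np
import pytest

from gastrosim import (
    BRAKE_DISABLED,
    GridSpec,
    MealSpec,
    SimulationConfig,
)


@pytest.fixture
def exponential_config():
    """Brake-free nutrient-only meal: StomN decays exactly exponentially."""
    return SimulationConfig(
        meal=MealSpec(nutrient_mass_0=20.0),
        feedback=BRAKE_DISABLED,
        K_a=0.0,
        gamma_0=1.0e-3,
        grid=GridSpec(dt=0.1, t_final=3600.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
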
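import numpy as np
import pytest

from thermopet import synthetic
from thermopet.kinetics import (
    ArrheniusTransition,
    DenaturationScheme,
    EquilibriumTwoState,
)


@pytest.fixture(scope="session")
def two_step_scheme():
    return synthetic.default_two_step_scheme()


@pytest.fixture(scope="session")
def one_step_scheme():
    return DenaturationScheme(
        "irreversible_one_step",
        transitions=(
            ArrheniusTransition("N->D", dH_cal=450e3, Ea=400e3, T_star=352.0),
        ),
    )


@pytest.fixture(scope="session")
def reversible_scheme():
    return DenaturationScheme(
        "reversible_two_state",
        equilibrium=EquilibriumTwoState(dH_vH=400e3, Tm_eq=348.0, dH_cal=450e3),
    )


@pytest.fixture(scope="session")
def grid_50_100C():
    """Standard acquisition grid: 50-100 degC at 0.2 K."""
    return np.arange(323.15, 373.15 + 0.1, 0.2)


@pytest.fixture(scope="session")
def noisy_series(two_step_scheme):
    """One noisy synthetic series reused by the fitting tests."""
    return synthetic.gen_thermogram_series(two_step_scheme, noise_sd=0.02, seed=7)
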
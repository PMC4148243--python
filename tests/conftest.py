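import numpy as np
import pytest

from pisaster_deb import (
    DEBParams,
    ForcingSeries,
    adult_state,
    default_params,
    integrate,
    reference_stage_marks,
    simulate_lifecycle,
)

T_12C = 285.15
T_13C = 286.15


@pytest.fixture(scope="session")
def params() -> DEBParams:
    return default_params()


@pytest.fixture(scope="session")
def marks(params):
    """Structural lengths at birth and metamorphosis under ad-libitum food."""
    return reference_stage_marks(params, T=T_12C, f=1.0)


@pytest.fixture(scope="session")
def lifecycle(params):
    """Full lifecycle at 12 degC, f = 1: embryo through puberty."""
    return simulate_lifecycle(params, T=T_12C, f=1.0, t_end=320.0, dt=0.01, dt_post=0.05)


@pytest.fixture(scope="session")
def steady_cycle(params, marks):
    """Well-fed mature adult over six annual spawning cycles at 13 degC."""
    init = adult_state(params, 250.0, *marks, e=1.0)
    forcing = ForcingSeries.constant(T=T_13C, f=1.0)
    return integrate(params, forcing, (0.0, 6 * 365.0), init, dt=0.1, dt_post=0.1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
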
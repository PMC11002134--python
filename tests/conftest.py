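import numpy as np
import pytest

from hrenergy import CouplingSpec, HRParams, IntegratorConfig


@pytest.fixture
def params():
    """Standard spiking-regime parameter set."""
    return HRParams(I_ext=1.0)


@pytest.fixture
def coupling():
    """Moderate mean-field coupling with a nonzero drive level."""
    return CouplingSpec(d1=0.5, k=2.0, x0=1.0)


@pytest.fixture
def random_states():
    """10^4 seeded random states spanning the attractor's scale."""
    rng = np.random.default_rng(42)
    return rng.uniform(-3.0, 3.0, size=(10_000, 3))


@pytest.fixture
def short_config():
    return IntegratorConfig(dt=0.01, total_time=100.0, burn_in=20.0)
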
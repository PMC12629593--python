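import numpy as np
import pytest

import fireflysync as ff


@pytest.fixture(scope="session")
def exp_density():
    """Shifted exponential IBI density: floor 5 s, rate 0.2 /s."""
    return ff.parametric_density(
        ff.ParametricIBIModel(family="shifted_exponential", t0=5.0, rate=0.2,
                              t_max=80.0))


@pytest.fixture(scope="session")
def exp_density_fine():
    """Same shifted exponential on a 0.01 s grid (resolves width 1/(N*rate)
    down to N = 50)."""
    return ff.parametric_density(
        ff.ParametricIBIModel(family="shifted_exponential", t0=5.0, rate=0.2,
                              t_max=80.0), grid_step=0.01)


@pytest.fixture(scope="session")
def lognormal_density():
    """Canonical broad synthetic IBI density (floor 5.672 s, median 30 s)."""
    return ff.parametric_density(ff.default_ibi_model())


@pytest.fixture(scope="session")
def uniform_density():
    """Uniform density on [8, 16] s."""
    t = np.arange(0, 20.01, 0.1)
    return ff.IBIDensity.from_values(t, ((t >= 8) & (t <= 16)).astype(float),
                                     t_min=8.0, t_max=16.0)


@pytest.fixture(scope="session")
def flash_density():
    return ff.default_flash_length_density()
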
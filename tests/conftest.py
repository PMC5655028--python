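import numpy as np
import pytest

from phypif.model import ModelConfig
from phypif.pif import integrate_pif

SEED = 1234  # canonical seed for every stochastic fixture


@pytest.fixture(scope="session")
def grid7():
    return np.linspace(0.0, 7.0, 701)


@pytest.fixture(scope="session")
def pif_traj(grid7):
    """Numeric PIF3 trajectory at default parameters on [0, 7] days."""
    return integrate_pif(grid=grid7)


@pytest.fixture(scope="session")
def default_config():
    return ModelConfig()
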
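import numpy as np
import pytest

from eesm import LIVER_PARAMS, LIVER_NU_IJ, MaterialParams


@pytest.fixture(scope="session")
def liver():
    """Porcine-liver constants from the cyclic uniaxial tests."""
    return LIVER_PARAMS


@pytest.fixture(scope="session")
def nu_ij():
    return LIVER_NU_IJ


@pytest.fixture(scope="session")
def iso_only():
    """Pure non-Gaussian matrix (f = 0), for mixture-degeneracy checks."""
    return MaterialParams(mu=0.1, N=1.1974)


@pytest.fixture(scope="session")
def lam_grid():
    return np.linspace(1.01, 1.29, 60)
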
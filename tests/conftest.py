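import numpy as np
import pytest

from prfconn.prf_fit import FitContext, FitOptions
from prfconn.prf_model import canonical_hrf
from prfconn.stimulus import build_bar_design, generate_aperture


@pytest.fixture(scope="session")
def design():
    return build_bar_design()


@pytest.fixture(scope="session")
def aperture(design):
    """Full-resolution aperture of the default protocol."""
    return generate_aperture(design, 101)


@pytest.fixture(scope="session")
def hrf():
    return canonical_hrf(1.0)


@pytest.fixture(scope="session")
def fit_context(aperture, hrf):
    """Shared grid-candidate predictions (expensive; built once per session)."""
    return FitContext(aperture, hrf, 2.0, FitOptions())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
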
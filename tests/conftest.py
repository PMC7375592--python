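import numpy as np
import pytest

from aseforecast.avalanche import compute_baseline, segment_avalanches
from aseforecast.models import MarginalParams, reference_shape, simulate_linear_response


@pytest.fixture(scope="session")
def marginal_series():
    """Long marginal-stability run (lambda = 1e-3), burn-in removed."""
    s = simulate_linear_response(MarginalParams(lam=1e-3, n_steps=10 ** 6, seed=42))
    return s.slice(1000, len(s))


@pytest.fixture(scope="session")
def marginal_catalog(marginal_series):
    return segment_avalanches(marginal_series, compute_baseline(marginal_series))


@pytest.fixture(scope="session")
def ref_shape():
    """Converged average avalanche shape of the marginal-stability model."""
    return reference_shape(lam=1e-3, n_steps=2_000_000, seed=0, cache_dir=None)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
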
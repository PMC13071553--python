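import numpy as np
import pytest

from refinemap.estimators import standardize
from refinemap.simulate import ar1_covariance, sample_gaussian_panel


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_panel(rng):
    """Standardized 200x4 Gaussian panel with AR(1) rho=0.5 LD."""
    raw = sample_gaussian_panel(200, ar1_covariance(4, 0.5), rng)
    return standardize(raw)


def random_psd(p, rng, jitter=0.1):
    """Random well-conditioned PSD matrix with unequal diagonal."""
    a = rng.standard_normal((p, p + 2))
    s = a @ a.T / (p + 2)
    return s + jitter * np.eye(p)
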
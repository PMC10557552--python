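import numpy as np
import pytest

from srdcor import PairedSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ar1_pair(rng):
    """A moderately autocorrelated paired series (both components AR(1), phi=0.6)."""
    n = 80
    x = np.empty(n)
    y = np.empty(n)
    sx = sy = 0.0
    for i in range(n):
        sx = 0.6 * sx + rng.standard_normal()
        sy = 0.6 * sy + rng.standard_normal()
        x[i], y[i] = sx, sy
    return PairedSeries(x, y)


@pytest.fixture
def iid_pair(rng):
    return PairedSeries(rng.standard_normal(60), rng.standard_normal(60))
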
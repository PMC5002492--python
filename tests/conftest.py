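import numpy as np
import pytest
from hypothesis import settings

import nutribalance as nb

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def basis():
    """Packaged complete 7-balance diagnostic basis."""
    return nb.default_basis()


@pytest.fixture(scope="session")
def partial_basis():
    """Same design without the completing row (forward ilr only)."""
    return nb.default_basis(complete=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(20160829)


def random_compositions(rng, n, d, scale=1000.0):
    """Strictly positive random compositions closed to ``scale``."""
    x = rng.dirichlet(np.full(d, 2.0), size=n) + 1e-6
    return x / x.sum(axis=1, keepdims=True) * scale
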
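import numpy as np
import pytest

from dmckit.model import DMCParameters, simulate_condition


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def simon_params():
    """Table-of-population-means Simon-like parameter vector."""
    return DMCParameters()


@pytest.fixture(scope="session")
def simon_batches():
    """One moderately large simulated Simon participant, shared across tests."""
    params = DMCParameters()
    rng = np.random.default_rng(99)
    return {
        c: simulate_condition(c, 10_000, params, rng)
        for c in ("congruent", "incongruent")
    }
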
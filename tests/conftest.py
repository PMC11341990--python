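import numpy as np
import pytest

from piyolo.data import generate_synthetic_sample


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def synthetic_batch():
    """Eight deterministic synthetic vessel patches."""
    rng = np.random.default_rng(7)
    return [generate_synthetic_sample(rng, n_vessels=int(rng.integers(1, 6)))
            for _ in range(8)]
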
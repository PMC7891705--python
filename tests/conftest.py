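import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20210218)


@pytest.fixture
def random_seqs(rng):
    """Factory: n uniform random barcode strings of length l."""
    from barcodeopt import factors

    def make(n, l, seed=None):
        r = rng if seed is None else np.random.default_rng(seed)
        return factors.decode(r.integers(0, 4, size=(n, l), dtype=np.uint8))

    return make
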
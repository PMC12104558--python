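import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def rng_factory():
    def make(seed: int) -> np.random.Generator:
        return np.random.default_rng(seed)

    return make
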
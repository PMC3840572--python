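import numpy as np
import pytest


@pytest.fixture
def rng():
    """Fresh deterministic generator for tests that only need one stream."""
    return np.random.default_rng(12345)
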
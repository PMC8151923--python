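import numpy as np
import pytest

from medfuse import build_pyramid_filters


@pytest.fixture(scope="session")
def fb():
    return build_pyramid_filters("9-7")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
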
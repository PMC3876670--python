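import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_image(rng):
    """A generic 16x16 random test image in [0, 1]."""
    return rng.random((16, 16))


@pytest.fixture(scope="session")
def phantom_pair():
    """One default phantom with its ground truth (session-cached)."""
    from mammopyr.phantom import PhantomSpec, generate

    return generate(PhantomSpec(seed=7))
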
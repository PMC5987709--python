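import numpy as np
import pytest

from perihalo.tracks import GradientFrame


@pytest.fixture
def gradient_x() -> GradientFrame:
    """Upgradient direction along +x."""
    return GradientFrame(direction=np.array([1.0, 0.0]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20180604)
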
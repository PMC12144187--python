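import numpy as np
import pytest

from pshglab import RatioTriple, TensorParams


@pytest.fixture
def grid18():
    """The standard 18-angle polarization grid, 0-170 degrees in 10-degree steps."""
    return np.arange(0.0, 180.0, 10.0)


@pytest.fixture
def example_params():
    """A typical collagen-like parameter set used across modules."""
    return TensorParams(alpha=30.0, A=1.0, B=1.1, C=0.5)


@pytest.fixture
def collagen_ratios():
    """Susceptibility ratios in the collagen range with their pitch angle."""
    return RatioTriple.from_ratios(1.13, 0.53)
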
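import numpy as np
import pytest

from tailsplit import GPDParams, WeibullParams


@pytest.fixture
def gpd_ref() -> GPDParams:
    """The light-tail reference case of the simulation study."""
    return GPDParams(0.8, 1.5)


@pytest.fixture
def weibull_ref() -> WeibullParams:
    return WeibullParams(3.0, 0.9)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20261001)
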
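import numpy as np
import pytest

from echopat.patterns import KernelSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def worked_kernel():
    """The published 3x3 worked-example window (row-major)."""
    return np.array([[135, 75, 75], [135, 75, 75], [160, 135, 135]], dtype=float)


@pytest.fixture
def k33():
    return KernelSpec(3, 3)
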
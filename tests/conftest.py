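import numpy as np
import pytest

from poolperm import DifferenceMatrix, PoolFrequencyTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_table():
    """3 markers x 4 pooling sets, candidate first."""
    rng = np.random.default_rng(7)
    return PoolFrequencyTable(
        markers=("candidate", "null_1", "null_2"),
        p1=rng.uniform(0.2, 0.8, size=(3, 4)),
        p0=rng.uniform(0.2, 0.8, size=(3, 4)),
    )


@pytest.fixture
def toy_dmatrix(rng):
    """11 markers x 8 sets of realistic-scale frequency differences."""
    return DifferenceMatrix(D=rng.normal(0.0, 0.05, size=(11, 8)))
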
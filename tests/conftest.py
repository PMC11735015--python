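import numpy as np
import pytest

from hragree.sync import AlignedPair


@pytest.fixture
def pair_factory():
    """Build an AlignedPair directly from test/criterion arrays."""

    def make(test, criterion):
        test = np.asarray(test, dtype=float)
        criterion = np.asarray(criterion, dtype=float)
        return AlignedPair(
            grid_times=np.arange(len(test), dtype=float),
            test_hr=test,
            criterion_hr=criterion,
            lag_applied=0,
        )

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
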
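import numpy as np
import pytest

from oscnet.montage import (
    Montage,
    fixture_montage_60,
    fixture_neighbor_threshold,
    neighbor_pairs,
)


@pytest.fixture(scope="session")
def cap60():
    """The packaged 60-channel reference cap."""
    return fixture_montage_60()


@pytest.fixture(scope="session")
def cap60_threshold(cap60):
    return fixture_neighbor_threshold(cap60)


@pytest.fixture(scope="session")
def pair_index_60(cap60, cap60_threshold):
    """PairIndex with the calibrated 192-neighbor exclusion."""
    return neighbor_pairs(cap60, cap60_threshold)


@pytest.fixture
def square_montage():
    """Four sensors on a square.

    After unit-mean-radius normalization the edges have length sqrt(2)
    and the diagonals 2, so any threshold between those marks exactly
    the four edges as neighbors.
    """
    pos = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [1.0, 1.0, 0.0],
            [0.0, 1.0, 0.0],
        ]
    )
    return Montage(("a", "b", "c", "d"), pos)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
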
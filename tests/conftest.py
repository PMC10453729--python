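import numpy as np
import pytest

from mism import BinaryMask, counts_from_cells


@pytest.fixture
def paper_weak_label_counts():
    """The worked weak-label example: N=60000, P=0, FP=5000, TN=55000."""
    return counts_from_cells(tp=0, fp=5000, tn=55000, fn=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20230808)


def random_mask(rng, shape):
    return BinaryMask(rng.random(shape) < 0.5)


@pytest.fixture
def enumerate_small_counts():
    """All count vectors with cells in 0..6, excluding the all-zero vector."""
    def _gen():
        for tp in range(7):
            for fp in range(7):
                for tn in range(7):
                    for fn in range(7):
                        if tp + fp + tn + fn > 0:
                            yield counts_from_cells(tp, fp, tn, fn)
    return _gen
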
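import numpy as np
import pytest

from craniofcm import worked_example_fixture


@pytest.fixture
def worked_example():
    """Three 2-D samples, two centres, initial memberships (0.7, 0.6, 0.2)."""
    return worked_example_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_valid_partition(rng, c, n):
    M = rng.random((c, n)) + 1e-3
    M /= M.sum(axis=0, keepdims=True)
    return M
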
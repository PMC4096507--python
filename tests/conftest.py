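import numpy as np
import pytest

from dietnet import DietMatrix


def make_matrix(counts, season="test"):
    counts = np.asarray(counts)
    ind = [f"w{i+1:02d}" for i in range(counts.shape[0])]
    tax = [f"t{j+1:02d}" for j in range(counts.shape[1])]
    return DietMatrix.validated(counts, ind, tax, season=season)


@pytest.fixture
def toy_matrix():
    """3 individuals x 3 taxa with distinct diets and no zero margins."""
    return make_matrix([[4, 1, 0], [1, 3, 1], [0, 1, 4]])


@pytest.fixture
def identical_diets():
    return make_matrix([[4, 2, 2], [4, 2, 2], [4, 2, 2]])
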
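import numpy as np
import pytest

from bilap import AssociationMatrix, BidirectionalLabelPropagation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_2x3():
    """The 2-disease x 3-microbe instance used across hand computations."""
    return AssociationMatrix(["d1", "d2"], ["m1", "m2", "m3"],
                             np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0]]))


@pytest.fixture
def toy_2x2():
    """2x2 matrix [[1,1],[1,0]] with a single negative pair (d2, m2)."""
    return AssociationMatrix(["d1", "d2"], ["m1", "m2"],
                             np.array([[1.0, 1.0], [1.0, 0.0]]))


@pytest.fixture
def small_estimator():
    """Estimator usable on matrices with as few as 2 nodes per side."""
    return BidirectionalLabelPropagation(k_neighbors=0)


@pytest.fixture
def assoc_file(tmp_path):
    """Factory writing a TSV association file and returning its path."""

    def _write(lines, name="assoc.tsv"):
        path = tmp_path / name
        path.write_text("".join(line + "\n" for line in lines))
        return str(path)

    return _write


def random_stochastic_network(rng, n, zero_diag=True):
    """Random row-stochastic matrix (zero diagonal) for propagation tests."""
    S = rng.random((n, n))
    if zero_diag:
        np.fill_diagonal(S, 0.0)
    return S / S.sum(axis=1, keepdims=True)
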
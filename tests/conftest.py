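import numpy as np
import pytest

from ipca import DataMatrix, center


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_centered(rng):
    """A small deterministic centered matrix (8 samples x 5 variables)."""
    x = rng.standard_normal((8, 5)) * [1.0, 2.0, 0.5, 3.0, 1.5]
    return center(DataMatrix(values=x))


@pytest.fixture
def laplace_rotation(rng):
    """Two unit-variance Laplace sources mixed by a 30-degree rotation.

    Returns ``(mixed, sources)`` with shapes (2, q).
    """
    q = 4000
    sources = rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=(2, q))
    theta = np.radians(30.0)
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    return rot @ sources, sources


def best_abs_corr(recovered, truth):
    """Max |correlation| of each true signal with any recovered one."""
    m = truth.shape[0]
    corr = np.corrcoef(truth, recovered)[:m, m:]
    return np.abs(corr).max(axis=1)
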
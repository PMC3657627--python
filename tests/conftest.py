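import numpy as np
import pytest

from rsnselect import SelectionConfig, make_decomposition
from rsnselect.model import ICADecomposition


@pytest.fixture(scope="session")
def default_fixture():
    """One default-parameter synthetic decomposition, shared read-only."""
    return make_decomposition(seed=0)


@pytest.fixture
def small_decomposition():
    """Tiny hand-built decomposition: 2 components on a 3x3x2 grid."""
    rng = np.random.default_rng(42)
    mask = np.ones((3, 3, 2), dtype=bool)
    mask[0, 0, 0] = False
    m = int(mask.sum())
    mixing = rng.normal(size=(16, 2))
    sources = rng.normal(size=(2, m))
    return ICADecomposition(mixing=mixing, sources=sources, mask=mask, tr_seconds=2.0)


@pytest.fixture
def cfg():
    return SelectionConfig()
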
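import numpy as np
import pytest

from bayescor import CountMatrix, toy_fixtures


@pytest.fixture(scope="session")
def toys():
    """The built-in reference toy fixtures, keyed by name."""
    return {t.name: t for t in toy_fixtures()}


@pytest.fixture()
def rng():
    return np.random.default_rng(20160929)


def random_count_matrix(rng, m=12, k=5, max_count=500, depth_span=(1e3, 1e5)):
    """A random integer count matrix with explicit heterogeneous depths."""
    counts = rng.integers(0, max_count, (m, k)).astype(float)
    depths = np.maximum(
        rng.uniform(*depth_span, k), counts.sum(axis=0))
    return CountMatrix(counts, column_totals=depths)
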
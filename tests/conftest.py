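import numpy as np
import pytest

from seqgnped.datasets import sim_qc
from seqgnped.qc import QcMatrix


@pytest.fixture(scope="session")
def qc21():
    """The bundled 21-item, K=5 simulation Q_c."""
    return sim_qc()


@pytest.fixture
def random_qc():
    """Factory for random small Q_c matrices (nonzero category rows)."""

    def make(rng, n_items=None, K=None, max_cats=3):
        n_items = n_items or rng.integers(2, 7)
        K = K or rng.integers(2, 6)
        cats = []
        for _ in range(n_items):
            S_j = rng.integers(1, max_cats + 1)
            item = []
            for _ in range(S_j):
                q = rng.integers(0, 2, size=K)
                if q.sum() == 0:
                    q[rng.integers(K)] = 1
                item.append(q)
            cats.append(item)
        return QcMatrix.from_arrays(cats)

    return make
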
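import numpy as np
import pytest

from fnconn.network import FNCMatrix
from fnconn.timecourses import RSN_LABELS


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_fnc(weights, retained=None, neuronal=None, labels=None) -> FNCMatrix:
    """Assemble an FNCMatrix directly from arrays (bypassing build_fnc)."""
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    if retained is None:
        retained = weights > 0
    if neuronal is None:
        neuronal = np.ones(n, dtype=bool)
    if labels is None:
        labels = list(RSN_LABELS[:n]) if n <= 10 else [f"n{k}" for k in range(n)]
    return FNCMatrix(
        labels=labels,
        weights=weights,
        retained=np.asarray(retained, dtype=bool),
        neuronal=np.asarray(neuronal, dtype=bool),
    )


def random_fnc(rng, n_nodes=8, density=0.5) -> FNCMatrix:
    """Random symmetric weighted graph with a matching retention mask."""
    w = np.zeros((n_nodes, n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < density:
                w[i, j] = w[j, i] = rng.uniform(0.1, 1.0)
    return make_fnc(w)
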
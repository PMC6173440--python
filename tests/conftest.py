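import numpy as np
import pytest

from netfluct.connectome import StructuralConnectome, normalize_weights
from netfluct.synthetic import SyntheticConnectomeSpec, generate_connectome


@pytest.fixture(scope="session")
def small_connectome() -> StructuralConnectome:
    """Deterministic 5-node toy connectome (a weighted ring plus one chord)."""
    n = 5
    w = np.zeros((n, n))
    edges = [(0, 1, 2.0), (1, 2, 4.0), (2, 3, 1.0), (3, 4, 3.0), (4, 0, 2.5),
             (1, 3, 0.5)]
    lengths = np.zeros((n, n))
    for i, j, v in edges:
        w[i, j] = w[j, i] = v
        lengths[i, j] = lengths[j, i] = 10.0 * (i + j + 1)
    return StructuralConnectome(weights=w, lengths=lengths)


@pytest.fixture(scope="session")
def modular_connectome() -> StructuralConnectome:
    """Seeded 40-node, 4-module synthetic connectome (normalized)."""
    return generate_connectome(
        SyntheticConnectomeSpec(n_nodes=40, n_modules=4, seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
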
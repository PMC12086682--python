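import numpy as np
import pytest

from mdmflow import WeightMatrix, build_chain, gaussian_kernel
from mdmflow.mdm import KernelParams


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_bimodal(rng):
    """Two 3-cluster modalities over 60 cells; cluster structure differs
    between modalities so weights are non-trivial."""
    C = 60
    labels = np.repeat([0, 1, 2], C // 3)
    m1 = rng.normal(size=(C, 3)) * 0.3 + np.array([[2.0, 0, 0]]) * labels[:, None]
    m2 = rng.normal(size=(C, 4)) * 0.3
    m2[:, 1] += (labels == 2) * 3.0
    return [m1, m2], labels


def make_chain(rng, C=40, M=2, n_kernel=5, dims=3):
    """Random multimodal chain for operator-level tests."""
    embeddings = [rng.normal(size=(C, dims)) for _ in range(M)]
    w = rng.dirichlet(np.ones(M), size=C)
    params = KernelParams(n_kernel, n_kernel)
    kernels = [gaussian_kernel(e, params) for e in embeddings]
    return build_chain(kernels, WeightMatrix(w)), embeddings, w


@pytest.fixture
def random_chain(rng):
    chain, _, _ = make_chain(rng)
    return chain
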
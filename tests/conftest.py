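import numpy as np
import pytest

from plps.patterns import CONSTANT, BinaryDataset, Pattern, build_design


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def toy_data(rng):
    """Small random binary dataset with a weak planted main effect."""
    n, p = 80, 6
    X = (rng.random((n, p)) < 0.5).astype(int)
    logit = -0.5 + 1.0 * X[:, 0]
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
    return BinaryDataset(y=y, X=X)


@pytest.fixture
def toy_design(toy_data):
    pats = [CONSTANT] + [Pattern((j,)) for j in range(toy_data.p)]
    return build_design(toy_data, pats)


def random_binary_dataset(rng, n, p, prevalence=0.4):
    X = (rng.random((n, p)) < 0.5).astype(int)
    y = (rng.random(n) < prevalence).astype(float)
    if y.sum() == 0:
        y[0] = 1.0
    if y.sum() == n:
        y[0] = 0.0
    return BinaryDataset(y=y, X=X)
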
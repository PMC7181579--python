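import numpy as np
import pytest

from igmod import models


def random_tensor(rng, max_count=50):
    """A random 3x3x2 count tensor with both disease strata populated."""
    while True:
        c = rng.integers(0, max_count + 1, size=(3, 3, 2))
        if c.sum() >= 2 and c[..., 0].sum() > 0 and c[..., 1].sum() > 0:
            return c


@pytest.fixture(scope="session")
def fixture_counts():
    """Deterministic fully-populated tensor used for frozen oracle checks."""
    rng = np.random.default_rng(7)
    return rng.integers(1, 30, size=(3, 3, 2))


@pytest.fixture(scope="session")
def epistasis01():
    return models.solve_model_params("epistasis", 0.1)


@pytest.fixture(scope="session")
def multiplicative02():
    return models.solve_model_params("multiplicative", 0.2)
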
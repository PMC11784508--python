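import numpy as np
import pytest

from optibias.model import (
    DirichletCounts,
    GenerativeModel,
    Modality,
    StateFactor,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_single_factor_model(prior, A, learnable_a=False, horizon=1, B=None):
    """One-factor, one-modality model used across the unit tests."""
    prior = np.asarray(prior, dtype=float)
    A = np.asarray(A, dtype=float)
    n = prior.shape[0]
    if B is None:
        B = np.eye(n)[:, :, None]
    factor = StateFactor("state", DirichletCounts(prior, learnable=False), B)
    modality = Modality("outcome", DirichletCounts(A, learnable=learnable_a))
    return GenerativeModel(
        factors=[factor],
        modalities=[modality],
        policies=np.zeros((1, max(horizon - 1, 0), 1), int),
        horizon=horizon,
    )


def random_model(rng, n_states=None, n_outcomes=None):
    """Random small single-factor model with Dirichlet-sampled columns."""
    n_states = n_states or int(rng.integers(2, 5))
    n_outcomes = n_outcomes or int(rng.integers(2, 5))
    A = rng.dirichlet(np.ones(n_outcomes), size=n_states).T
    prior = rng.dirichlet(np.ones(n_states))
    return make_single_factor_model(prior, A)


@pytest.fixture
def single_factor_model_factory():
    return make_single_factor_model


@pytest.fixture
def random_model_factory():
    return random_model
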
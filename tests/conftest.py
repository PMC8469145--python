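import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_model():
    from bmem import build_gaussian_model

    return build_gaussian_model(1.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def default_categorical():
    from bmem import build_categorical_model

    return build_categorical_model(1.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def perturbed_relaxation(default_model):
    """The canonical perturbation experiment, shared across measure tests."""
    from bmem import perturbed_initial_density, propagate_density

    state0 = perturbed_initial_density(default_model)
    return propagate_density(default_model, state0, dt=1 / 64, T=16.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20210825)


def random_spd(rng, n=3, scale=1.0):
    """Random symmetric positive-definite matrix."""
    M = rng.standard_normal((n, n))
    return scale * (M @ M.T + n * np.eye(n))
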
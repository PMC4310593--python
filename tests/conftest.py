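import numpy as np
import pytest
from hypothesis import settings

import ectimetry as em

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def flat_model():
    return em.BoundaryModel(baseline_depth=150.0)


@pytest.fixture(scope="session")
def sine_model():
    return em.BoundaryModel(baseline_depth=150.0, sine_amplitude=20.0, sine_period=80.0)


@pytest.fixture(scope="session")
def noiseless_params():
    return em.PhantomParams(noise=em.NoiseModel(gaussian_sd=0.0, poisson_gain=0.0),
                            rng_seed=1)


@pytest.fixture(scope="session")
def flat_section(flat_model, noiseless_params):
    section, truth = em.render_phantom(noiseless_params, flat_model)
    return section, truth


@pytest.fixture(scope="session")
def noisy_flat_section(flat_model):
    section, truth = em.render_phantom(em.PhantomParams(rng_seed=2), flat_model)
    return section, truth


@pytest.fixture(scope="session")
def noisy_sine_section(sine_model):
    section, truth = em.render_phantom(em.PhantomParams(rng_seed=3), sine_model)
    return section, truth


def semicircle_points(radius=50.0, n=100_000, x0=0.0, z0=150.0):
    """Dense polyline of a semicircular interface bulging downward."""
    theta = np.linspace(np.pi, 0.0, n)
    x = x0 + radius + radius * np.cos(theta)
    z = z0 + radius * np.sin(theta)
    return np.column_stack([x, z])
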
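import numpy as np
import pytest

from pulseflow import CohortSpec, PhantomSpec, generate_cohort, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """A small, short phantom shared by tests that only need plausibility."""
    spec = PhantomSpec(grid_shape=(20, 20, 20), duration_s=10.0, seed=5)
    series, truth = generate_phantom(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A three-subject cohort at reduced grid size, shared across tests."""
    spec = CohortSpec(
        n_subjects=3, grid_shape=(24, 24, 24), duration_s=60.0,
        noise_sd=0.005, seed=7,
    )
    return spec, generate_cohort(spec)


def gaussian_blob(shape, center, sigma=2.5):
    """Smooth test volume: an isotropic Gaussian blob."""
    idx = np.indices(shape, dtype=float)
    d2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
    return np.exp(-0.5 * d2 / sigma**2)
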
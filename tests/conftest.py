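import numpy as np
import pytest

from emovar import (
    SimConfig,
    center_scores,
    asymmetric_distances,
    gen_dimension_scores,
    gen_structured_params,
    simulate_panel,
)


@pytest.fixture(scope="session")
def small_config():
    """A quick-to-simulate system: 6 emotions, 200 days, 2 dimensions."""
    return SimConfig(
        n_emotions=6, n_days=200, n_dims=2, n_exog=1,
        exog_break_fractions=(0.8,), burn_in=100, seed=11,
    )


@pytest.fixture(scope="session")
def small_system(small_config):
    dims = gen_dimension_scores(small_config)
    truth, coeffs = gen_structured_params(dims, small_config)
    return dims, truth, coeffs


@pytest.fixture(scope="session")
def small_panel(small_config, small_system):
    _, _, coeffs = small_system
    return simulate_panel(coeffs, small_config)


@pytest.fixture(scope="session")
def study_config():
    """The analysed design: 24 emotions, 790 days, 3 dimensions, 2 dummies."""
    return SimConfig(seed=5)


@pytest.fixture(scope="session")
def study_system(study_config):
    dims = gen_dimension_scores(study_config)
    truth, coeffs = gen_structured_params(dims, study_config)
    return dims, truth, coeffs


def centered_with_distances(dims):
    cdims = center_scores(dims)
    return cdims, asymmetric_distances(cdims)


def random_stationary_coeffs(rng, n, radius=0.85):
    """Unstructured stationary VAR(1) matrices for oracle checks."""
    from emovar import VARCoefficients

    g = rng.standard_normal((n, n)) / np.sqrt(n)
    g *= radius / np.max(np.abs(np.linalg.eigvals(g)))
    a = rng.uniform(0.01, 0.1, n)
    s = rng.standard_normal((n, n + 3))
    sigma = s @ s.T / (n + 3) * 1e-4
    return VARCoefficients(alpha=a, gamma=g, beta=np.zeros((n, 0)), sigma=sigma)
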
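import numpy as np
import pytest

from popcode import PopulationStats
from popcode._linalg import random_pd


def make_random_stats(
    rng: np.random.Generator, n_neurons: int, stim_dim: int = 1, consistent: bool = True
) -> PopulationStats:
    """Random well-posed statistics.

    With ``consistent=True`` the mean-response covariance is built as
    ``L Cs^{-1} L^T + P`` with P positive definite, so the joint Gaussian
    consistency constraint holds (strictly) for every admissible noise
    covariance — mutual information stays finite across the spectrahedron.
    """
    l = rng.standard_normal((n_neurons, stim_dim))
    cs = random_pd(rng, stim_dim)
    p = random_pd(rng, n_neurons)
    if consistent:
        cmu = l @ np.linalg.solve(cs, l.T) + p
    else:
        cmu = p
    f = rng.standard_normal((n_neurons, stim_dim))
    nv = rng.uniform(0.5, 2.0, n_neurons)
    return PopulationStats(
        sensitivities=f, cross_cov=l, mean_resp_cov=cmu, noise_vars=nv, stim_cov=cs
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240227)


@pytest.fixture
def random_stats():
    return make_random_stats
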
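import numpy as np
import pytest

from agemix.densities import NormalParams, sample_density


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def bimodal_ages():
    """5000 ages from 0.7*N(45, 8^2) + 0.3*N(65, 6^2), fixed seed."""
    r = np.random.default_rng(777)
    return np.concatenate([r.normal(45, 8, 3500), r.normal(65, 6, 1500)])


@pytest.fixture(scope="session")
def unimodal_ages():
    r = np.random.default_rng(778)
    return r.normal(55, 9, 2000)


def truncated_mixture_sample(n, p_early, seed, mu_early=46.0, sd_early=9.0,
                             mu_late=67.0, sd_late=7.0, window=(20.0, 74.0)):
    """Component-labelled draw from a truncated two-component normal
    mixture (latent label first, rejection within the component)."""
    r = np.random.default_rng([seed, 0])
    early = r.random(n) < p_early
    ne = int(early.sum())
    ages = np.empty(n)
    if ne:
        ages[early] = sample_density(
            NormalParams(mu_early, sd_early), ne, [seed, 1], truncation=window
        )
    if n - ne:
        ages[~early] = sample_density(
            NormalParams(mu_late, sd_late), n - ne, [seed, 2],
            truncation=window,
        )
    return ages, early
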
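"""Shared fixtures: the default synthetic scenario at the study sizes.

The heavy simulated datasets are session-scoped so the oracle-equivalence,
bias-correction and sensitivity tests share one generation + fit.
"""

import warnings

import numpy as np
import pytest

from adprev.pipeline import PipelineConfig, fit_staged
from adprev.synth import (
    default_params,
    fully_observed_params,
    generate_population,
    simulate_observation,
)


@pytest.fixture(scope="session")
def params_default():
    return default_params()


@pytest.fixture(scope="session")
def fully_observed_200k(params_default):
    """Fully observed population, n = 200 000 (participation == 1)."""
    p = fully_observed_params(params_default)
    pop = generate_population(p, 200_000, seed=0)
    obs = simulate_observation(pop, p, seed=1)
    return p, pop, obs


@pytest.fixture(scope="session")
def fit_fully_observed(fully_observed_200k):
    _, _, obs = fully_observed_200k
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_staged(obs, PipelineConfig())


@pytest.fixture(scope="session")
def observed_100k(params_default):
    """Default biased-participation scenario, population n = 100 000."""
    pop = generate_population(params_default, 100_000, seed=0)
    obs = simulate_observation(pop, params_default, seed=1)
    return pop, obs


@pytest.fixture(scope="session")
def fit_ipw_100k(observed_100k):
    _, obs = observed_100k
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_staged(obs, PipelineConfig(use_ipw=True))


@pytest.fixture(scope="session")
def fit_unweighted_100k(observed_100k):
    _, obs = observed_100k
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_staged(obs, PipelineConfig(use_ipw=False))


@pytest.fixture(scope="session")
def small_observed(params_default):
    """A small observed cohort for fast structural tests."""
    pop = generate_population(params_default, 6000, seed=5)
    return simulate_observation(pop, params_default, seed=6)


def sex_average(fn) -> np.ndarray:
    """Average a per-sex curve function over sexes (population is ~50/50)."""
    return 0.5 * (np.asarray(fn("female")) + np.asarray(fn("male")))
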
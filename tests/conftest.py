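import logging

import numpy as np
import pytest

from ethnosae import (Codebook, MODELLED_INDICATORS, default_truth, fit_glmm,
                      simulate)

logging.getLogger("ethnosae").setLevel(logging.ERROR)

#: fixture study conditions: six states of 2,000 women, 25% survey sampling
FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def truth_params():
    return default_truth(n_states=6, rows_per_state=2000, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_sim(truth_params):
    return simulate(truth_params, fractions=0.25, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def fitted_models(fixture_sim):
    return {ind: fit_glmm(fixture_sim.survey, ind)
            for ind in MODELLED_INDICATORS}


@pytest.fixture(scope="session")
def small_sim():
    params = default_truth(n_states=3, rows_per_state=800, seed=5)
    return simulate(params, fractions=0.3, seed=5)


def make_simple_truth(n_states=14, rows_per_state=300, sigma=0.5,
                      beta0=0.0, seed=0):
    """Reduced study conditions: intercept + mother + education only,
    common sigma_v; useful where many fast refits are needed."""
    cb = Codebook(("is_mother", "education"))
    beta = {"intercept": beta0, "is_mother": 0.3, "edu_primary": 0.2,
            "edu_secondary": 0.4, "edu_higher": 0.5}
    params = default_truth(n_states, rows_per_state, seed)
    params.codebook = cb
    params.beta = {ind: dict(beta) for ind in MODELLED_INDICATORS}
    params.sigma_v = {ind: sigma for ind in MODELLED_INDICATORS}
    return params


def population_as_survey(population):
    """Treat a full synthetic population as a self-weighting survey."""
    df = population.copy()
    df["weight"] = 1.0
    return df
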
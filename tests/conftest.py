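"""Shared fixtures.

The two full-scale Gibbs fits (change-point and Markov, 301 x 30 at the
reduced 1,000 + 1,000 sampler protocol) are session-scoped because several
tests interrogate different aspects of the same posterior.
"""

import warnings

import numpy as np
import pytest

from respshift import (
    GibbsConfig,
    SimulationConfig,
    get_scenario,
    gibbs_fit_changepoint,
    gibbs_fit_markov,
    simulate_joint,
    simulate_mixture_rasch,
)

DESK_CONFIG = GibbsConfig(n_chains=2, burn_in=1000, n_iter=1000, seed=5)


@pytest.fixture(scope="session")
def cp_sim():
    """Late-shift change-point dataset: 301 x 30, late transitions,
    residual variances (0.187, 1.647), erratic accuracy .26."""
    return simulate_joint(get_scenario("late_shift_cp"), seed=11)


@pytest.fixture(scope="session")
def cp_fit(cp_sim):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gibbs_fit_changepoint(cp_sim.dataset, DESK_CONFIG, mode="residual")


@pytest.fixture(scope="session")
def markov_sim():
    return simulate_joint(get_scenario("late_shift_markov"), seed=11)


@pytest.fixture(scope="session")
def markov_fit(markov_sim):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gibbs_fit_markov(markov_sim.dataset, DESK_CONFIG)


@pytest.fixture(scope="session")
def anchored_null_sim():
    """No 1->2 transitions; only the small initial erratic population
    (5.2% of examinees at item 1, decaying) carries state 2."""
    cfg = SimulationConfig(
        structure="markov",
        initial_probs=(0.948, 0.052),
        transition_matrix=((1.0, 0.0), (0.07, 0.93)),
        erratic_accuracy=0.26,
    )
    return simulate_joint(cfg, seed=4)


@pytest.fixture(scope="session")
def anchored_null_fit(anchored_null_sim):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gibbs_fit_markov(
            anchored_null_sim.dataset,
            GibbsConfig(n_chains=2, burn_in=800, n_iter=800, seed=1),
        )


@pytest.fixture(scope="session")
def two_class_sim():
    return simulate_mixture_rasch(get_scenario("two_class_mixture"), seed=9)
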
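import math

import numpy as np
import pytest

import delaydisc as dd
from delaydisc.hierarchical_inference import MCMCConfig


@pytest.fixture(scope="session")
def adolescent_hypers():
    """Seconds-scale operating point: median k near the grid's indifference
    region, softmax beta ~ e (per cent of value difference)."""
    return dd.GroupHyperParams(mu_log_k=math.log(0.03), sigma_log_k=1.0,
                               mu_beta_raw=1.0, sigma_beta_raw=0.5)


@pytest.fixture(scope="session")
def adult_hypers():
    """Days-scale operating point: median k = 0.01/day, beta ~ 0.2/euro."""
    return dd.GroupHyperParams(mu_log_k=math.log(0.01), sigma_log_k=1.0,
                               mu_beta_raw=math.log(0.2), sigma_beta_raw=0.5)


@pytest.fixture(scope="session")
def small_adolescent_cohort(adolescent_hypers):
    """Two groups x 6 subjects on the 50-trial grid, with a 1.0 log-k shift."""
    shifted = dd.GroupHyperParams(mu_log_k=adolescent_hypers.mu_log_k - 1.0,
                                  sigma_log_k=1.0, mu_beta_raw=1.0,
                                  sigma_beta_raw=0.5)
    spec = dd.CohortSpec(n_per_group=6, design="adolescent_grid",
                         group_hypers={"patients": shifted,
                                       "controls": adolescent_hypers},
                         seed=20240901)
    return dd.simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_adult_cohort(adult_hypers):
    spec = dd.CohortSpec(n_per_group=5, design="adult_pretest",
                         group_hypers={"patients": adult_hypers,
                                       "controls": adult_hypers},
                         seed=20240902)
    return dd.simulate_cohort(spec)


@pytest.fixture(scope="session")
def quick_mcmc():
    """Short chains for structural tests where convergence is not asserted."""
    return MCMCConfig(n_chains=2, n_iter=900, n_burnin=400, base_seed=17)


@pytest.fixture(scope="session")
def small_fit(small_adolescent_cohort):
    cfg = MCMCConfig(n_chains=2, n_iter=2500, n_burnin=1000, base_seed=33)
    return dd.fit_hierarchical(small_adolescent_cohort, "hyperbolic", cfg=cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
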
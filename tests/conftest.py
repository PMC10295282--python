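import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dinmix as dm

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_covs(rng):
    """2 sites × 2 surveys, one covariate per level, already z-scored."""
    return dm.CovariateSet(rng.normal(size=(2, 1)), rng.normal(size=(2, 2, 1)),
                           ("M",), ("D",), standardized=True)


@pytest.fixture
def small_params(rng):
    p = dm.ModelParams(alpha_A=rng.normal(0, 0.5, 2), alpha_B=rng.normal(0, 0.5, 2),
                       beta_A=rng.normal(0, 0.5, 2), beta_B=rng.normal(0, 0.5, 2),
                       gamma=-0.2, epsilon=-1.0)
    p = p.with_dims(2, 2)
    p.eta_A = rng.normal(0, 0.3, 2)
    p.eta_B = rng.normal(0, 0.3, 2)
    p.delta_A = rng.normal(0, 0.3, (2, 2))
    p.delta_B = rng.normal(0, 0.3, (2, 2))
    return p


@pytest.fixture(scope="session")
def quick_fit():
    """One small but real fit shared by sampler/ppc/summary tests.

    Informative truth (p ≈ 0.6, lambda = 2) on 20 sites so every parameter
    carries likelihood information; short chains keep it fast.
    """
    design = dm.DesignSpec(n_sites=20, n_surveys=3, survey_site_jitter=1.0)
    truth = dm.ModelParams(
        alpha_A=np.array([0.4, 0.3, -0.2, 0.1]),
        alpha_B=np.array([0.2, -0.3, 0.2, 0.0]),
        beta_A=np.array([np.log(2.0), 0.3, -0.2, 0.1]),
        beta_B=np.array([np.log(2.0), -0.2, 0.3, 0.0]),
        gamma=-0.1, epsilon=-1.0,
        sigma_eta_A=0.3, sigma_eta_B=0.3, sigma_delta_A=0.3, sigma_delta_B=0.3)
    sim = dm.simulate(design, truth, seed=11)
    cfg = dm.MCMCConfig.desk(seed=5, n_adapt=1000, n_iter=3000, n_burn=500, thin=5)
    draws = dm.run_mcmc(sim.data, sim.covs, dm.PriorSpec(), cfg, force=True)
    return sim, draws
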
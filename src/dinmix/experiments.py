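"""Canned validation experiments shared by the test suite, the acceptance
script and the analysis drivers.

Each experiment fixes a study condition (design, generating truth, fit
protocol) and derives every internal seed from one master seed, so a single
integer reproduces the whole run.  Conditions:

* ``neutral_recovery`` — null calibration: all fixed effects zero (p = 1/2,
  lambda = 1, no interactions), sigma = 0.5, 40 sites × 3 surveys, reduced
  fit protocol; 90% HDIs should cover the generating values at roughly the
  nominal rate.
* ``sign_detection`` — power check for the co-detection term: the study's
  point estimates as truth (epsilon = −3.76, gamma = −0.18) at five times
  the study's plot count (130 sites); the posterior for epsilon should be
  reliably negative.
* ``ppc_calibration`` — Bayesian p-values on well-specified data should be
  spread over the unit interval, and a gross single-cell corruption (+20)
  should push the affected species' p-value toward 0.
* ``well_behaved_fit`` — one informative fit (p ≈ 0.6, lambda = 2, modest
  slopes) on which every monitored parameter should converge (R̂ < 1.1)
  under the reduced protocol.

Survey covariates are drawn per cell (``survey_site_jitter = 1``) in these
experiments, for two reasons.  First, with only three shared occasion
values two survey covariates are frequently near-collinear by chance,
which the package's own screen would veto.  Second, identification: when
survey covariates take one value per occasion, the co-detection term
``epsilon * p_A`` varies across occasions almost exactly like the
receiver's own occasion-level detection predictor, so ``epsilon`` is close
to unidentified no matter how many sites are surveyed; per-cell variation
in ``p_A`` is what carries the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import ModelParams, PriorSpec
from .ppc import bayesian_pvalue
from .sampler import MCMCConfig, run_mcmc, summarize
from .synthetic import (DesignSpec, RecoveryResult, default_truth,
                        neutral_truth, recovery_experiment, simulate)

__all__ = [
    "neutral_recovery",
    "sign_detection",
    "ppc_calibration",
    "well_behaved_fit",
    "informative_truth",
    "PPCCalibrationResult",
]


def informative_truth() -> ModelParams:
    """A well-identified regime: p ≈ 0.6, lambda = 2, modest covariate
    effects, small random-effect SDs."""
    return ModelParams(
        alpha_A=np.array([0.4, 0.3, -0.2, 0.1]),
        alpha_B=np.array([0.2, -0.3, 0.2, 0.1]),
        beta_A=np.array([np.log(2.0), 0.3, -0.2, 0.1]),
        beta_B=np.array([np.log(2.0), -0.2, 0.3, -0.1]),
        gamma=-0.1, epsilon=-1.0,
        sigma_eta_A=0.3, sigma_eta_B=0.3,
        sigma_delta_A=0.3, sigma_delta_B=0.3)


def neutral_recovery(seed: int, n_reps: int = 20) -> RecoveryResult:
    """Null-truth parameter recovery at 40 sites with the reduced protocol."""
    design = DesignSpec(n_sites=40, n_surveys=3, survey_site_jitter=1.0)
    truth = neutral_truth(sigma=0.5)
    cfg = MCMCConfig.desk()
    return recovery_experiment(design, truth, n_reps=n_reps, fit_config=cfg,
                               seed=seed)


def sign_detection(seed: int, n_reps: int = 10,
                   n_sites: int = 130) -> RecoveryResult:
    """Co-detection sign recovery at the study's point estimates, scaled to
    five times the study's plot count."""
    design = DesignSpec(n_sites=n_sites, n_surveys=3, survey_site_jitter=1.0)
    truth = default_truth()
    cfg = MCMCConfig.desk(n_adapt=1500, n_iter=4000, n_burn=1000, thin=3)
    return recovery_experiment(design, truth, n_reps=n_reps, fit_config=cfg,
                               seed=seed)


@dataclass
class PPCCalibrationResult:
    pvalues: pd.DataFrame       # per replicate, per species
    corrupted_p_A: float        # p-value for species A after +20 on one cell
    failures: list


def ppc_calibration(seed: int, n_reps: int = 20) -> PPCCalibrationResult:
    """Fit well-specified replicates and score their Bayesian p-values; then
    score a corrupted copy of the first replicate (+20 on one count cell of
    species A) against that replicate's fitted draws.

    The corrupted data are scored against the existing fit — the way a
    posterior predictive check is used to screen data against a model —
    rather than refitted: refitting lets the observation- and site-level
    random effects absorb a single wrecked cell entirely (eta for the site
    level, delta for the cell), which is a property of this model class,
    not a failure of the check.
    """
    design = DesignSpec(n_sites=26, n_surveys=3, survey_site_jitter=1.0)
    truth = informative_truth()
    cfg = MCMCConfig.desk(n_adapt=1000, n_iter=3000, n_burn=600, thin=3)
    ss = np.random.SeedSequence(seed).generate_state(3 * (n_reps + 1))
    rows, failures = [], []
    first = None
    for rep in range(n_reps):
        sim = simulate(design, truth, int(ss[3 * rep]) % 2**31)
        cfg_r = replace(cfg, seed=int(ss[3 * rep + 1]) % 2**31)
        try:
            draws = run_mcmc(sim.data, sim.covs, PriorSpec(), cfg_r, force=True)
            res = bayesian_pvalue(draws, sim.data, sim.covs,
                                  seed=int(ss[3 * rep + 2]) % 2**31)
        except Exception as exc:
            failures.append((rep, repr(exc)))
            continue
        if rep == 0:
            first = (sim, draws)
        rows.append({"rep": rep, "p_A": res.bayesian_p_A,
                     "p_B": res.bayesian_p_B})

    # gross-misfit detection: one wrecked cell in species A
    from .datamodel import CountData
    sim0, draws0 = first
    counts_A = sim0.data.counts_A.copy()
    counts_A[0, 0] += 20
    bad = CountData(counts_A, sim0.data.counts_B)
    res = bayesian_pvalue(draws0, bad, sim0.covs, seed=int(ss[-2]) % 2**31)
    return PPCCalibrationResult(pvalues=pd.DataFrame(rows),
                                corrupted_p_A=res.bayesian_p_A,
                                failures=failures)


def well_behaved_fit(seed: int):
    """One informative 40-site fit with the reduced protocol; returns
    ``(simulated dataset, draws, summary table)``."""
    design = DesignSpec(n_sites=40, n_surveys=3, survey_site_jitter=1.0)
    ss = np.random.SeedSequence(seed).generate_state(2)
    sim = simulate(design, informative_truth(), int(ss[0]) % 2**31)
    cfg = MCMCConfig.desk(seed=int(ss[1]) % 2**31)
    draws = run_mcmc(sim.data, sim.covs, PriorSpec(), cfg, force=True)
    return sim, draws, summarize(draws)
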
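"""Joint two-species N-mixture likelihood with directional interactions.

The observation model for each species is the static binomial N-mixture
model: site abundance ``N_i ~ Poisson(lambda_i)`` and repeated counts
``C_ij | N_i ~ Binomial(N_i, p_ij)``.  Two such models are stacked with two
directional interaction terms:

* co-abundance ``gamma`` — the latent abundance of species A enters the
  log-abundance predictor of species B (``... + gamma * N_iA``), so a
  negative ``gamma`` means sites holding many A hold fewer B (spatial
  segregation, the signature of exploitative competition);
* co-detection ``epsilon`` — the detection probability of species A enters
  the logit-detection predictor of species B (``... + epsilon * p_ijA``).
  Detection probability proxies surface activity, so a negative ``epsilon``
  means B is less active when A is active (temporal niche partitioning, the
  signature of interference competition).

Detection predictors carry survey-level covariates plus an observation-level
normal random effect ``delta_ij`` (extra-binomial noise); abundance
predictors carry site-level covariates plus a site-level normal random
effect ``eta_i`` (extra-Poisson noise).  Both discrete latent abundances are
marginalized out of the likelihood by truncated summation, so the posterior
is over continuous parameters only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy import stats

__all__ = [
    "ModelParams",
    "PriorSpec",
    "detect_prob_A",
    "detect_prob_B",
    "abundance_rate_A",
    "abundance_rate_B",
    "site_marginal_loglik",
    "all_site_logliks",
    "single_species_marginal_loglik",
    "total_log_posterior",
    "choose_truncation",
    "inv_logit",
    "logit",
]

PREDICTOR_LIMIT = 50.0  # |log-scale linear predictor| beyond this signals divergence
_LOGIT_CLAMP = 35.0     # keeps p strictly inside (0, 1) in double precision


def inv_logit(x):
    """Numerically safe logistic function."""
    x = np.clip(x, -_LOGIT_CLAMP, _LOGIT_CLAMP)
    return 1.0 / (1.0 + np.exp(-x))


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


# ---------------------------------------------------------------------------
# parameters and priors
# ---------------------------------------------------------------------------


@dataclass
class ModelParams:
    """Full continuous parameter vector of the stacked model.

    ``alpha_*`` are detection coefficients on the logit scale (intercept
    followed by one slope per survey covariate); ``beta_*`` are abundance
    coefficients on the log scale (intercept followed by one slope per site
    covariate).  ``gamma`` multiplies the raw latent integer ``N_iA`` in
    species B's abundance predictor; ``epsilon`` multiplies ``p_ijA`` on the
    probability scale in species B's detection predictor.  ``eta_*`` are
    per-site and ``delta_*`` per-site-per-survey normal random effects with
    standard deviations ``sigma_*``.
    """

    alpha_A: np.ndarray
    alpha_B: np.ndarray
    beta_A: np.ndarray
    beta_B: np.ndarray
    gamma: float = 0.0
    epsilon: float = 0.0
    eta_A: np.ndarray = None
    eta_B: np.ndarray = None
    delta_A: np.ndarray = None
    delta_B: np.ndarray = None
    sigma_eta_A: float = 0.5
    sigma_eta_B: float = 0.5
    sigma_delta_A: float = 0.5
    sigma_delta_B: float = 0.5

    def __post_init__(self):
        for name in ("alpha_A", "alpha_B", "beta_A", "beta_B"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("sigma_eta_A", "sigma_eta_B", "sigma_delta_A", "sigma_delta_B"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    def with_dims(self, n_sites: int, n_surveys: int) -> "ModelParams":
        """Return a copy with zero-filled random effects where unset."""
        out = replace(self)
        if out.eta_A is None:
            out.eta_A = np.zeros(n_sites)
        if out.eta_B is None:
            out.eta_B = np.zeros(n_sites)
        if out.delta_A is None:
            out.delta_A = np.zeros((n_sites, n_surveys))
        if out.delta_B is None:
            out.delta_B = np.zeros((n_sites, n_surveys))
        for name in ("eta_A", "eta_B"):
            if np.asarray(getattr(out, name)).shape != (n_sites,):
                raise ValueError(f"{name} has wrong length")
        for name in ("delta_A", "delta_B"):
            if np.asarray(getattr(out, name)).shape != (n_sites, n_surveys):
                raise ValueError(f"{name} has wrong shape")
        return out

    @property
    def coefficients(self) -> np.ndarray:
        """The 18 fixed effects in canonical order (alpha_A, alpha_B, beta_A,
        beta_B, gamma, epsilon)."""
        return np.concatenate([self.alpha_A, self.alpha_B, self.beta_A,
                               self.beta_B, [self.gamma, self.epsilon]])


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative priors: Normal(0, sd_coef) on every fixed effect
    (including gamma and epsilon), Uniform(0, sd_max) on each random-effect
    SD."""

    sd_coef: float = 10.0
    sd_max: float = 5.0

    def __post_init__(self):
        if not (self.sd_coef > 0 and self.sd_max > 0):
            raise ValueError("prior scales must be > 0")


# ---------------------------------------------------------------------------
# linear predictors (the four regression equations)
# ---------------------------------------------------------------------------


def detect_prob_A(alpha_A, survey_covs_ij, delta=0.0):
    """Detection probability of the donor species at one site × survey:
    ``logit(p) = a0 + a·x_ij + delta_ij``."""
    alpha_A = np.asarray(alpha_A, float)
    x = np.atleast_1d(np.asarray(survey_covs_ij, float))
    return float(inv_logit(alpha_A[0] + x @ alpha_A[1:] + delta))


def detect_prob_B(alpha_B, survey_covs_ij, p_A, epsilon, delta=0.0):
    """Detection probability of the receiver species; the donor's detection
    probability enters the logit predictor scaled by ``epsilon``."""
    if not 0.0 < p_A < 1.0:
        raise ValueError("p_A must lie in (0, 1)")
    alpha_B = np.asarray(alpha_B, float)
    x = np.atleast_1d(np.asarray(survey_covs_ij, float))
    return float(inv_logit(alpha_B[0] + x @ alpha_B[1:] + epsilon * p_A + delta))


def abundance_rate_A(beta_A, site_covs_i, eta=0.0):
    """Poisson mean of the donor species at one site:
    ``log(lambda) = b0 + b·x_i + eta_i``."""
    beta_A = np.asarray(beta_A, float)
    x = np.atleast_1d(np.asarray(site_covs_i, float))
    lin = beta_A[0] + x @ beta_A[1:] + eta
    if abs(lin) > PREDICTOR_LIMIT:
        raise OverflowError(f"abundance predictor {lin:.1f} exceeds ±{PREDICTOR_LIMIT}")
    return float(np.exp(lin))


def abundance_rate_B(beta_B, site_covs_i, N_A, gamma, eta=0.0):
    """Poisson mean of the receiver species; the donor's raw latent integer
    abundance enters the log predictor scaled by ``gamma``."""
    if N_A < 0 or N_A != int(N_A):
        raise ValueError("N_A must be a non-negative integer")
    beta_B = np.asarray(beta_B, float)
    x = np.atleast_1d(np.asarray(site_covs_i, float))
    lin = beta_B[0] + x @ beta_B[1:] + gamma * N_A + eta
    if abs(lin) > PREDICTOR_LIMIT:
        raise OverflowError(f"abundance predictor {lin:.1f} exceeds ±{PREDICTOR_LIMIT}")
    return float(np.exp(lin))


def build_predictors(params: ModelParams, covs):
    """Assemble the four predictor arrays for every site × survey cell.

    Returns ``(lp_A, lp_B0, llam_A, llam_B0)`` where ``lp_B0`` omits the
    ``epsilon * p_A`` term and ``llam_B0`` omits the ``gamma * N_A`` term —
    both are applied inside the marginal-likelihood kernel where ``p_A`` and
    ``N_A`` live.
    """
    xs = covs.site_covs
    xv = covs.survey_covs
    lp_A = params.alpha_A[0] + xv @ params.alpha_A[1:] + params.delta_A
    lp_B0 = params.alpha_B[0] + xv @ params.alpha_B[1:] + params.delta_B
    llam_A = params.beta_A[0] + xs @ params.beta_A[1:] + params.eta_A
    llam_B0 = params.beta_B[0] + xs @ params.beta_B[1:] + params.eta_B
    return lp_A, lp_B0, llam_A, llam_B0


# ---------------------------------------------------------------------------
# marginal likelihood kernel (numba)
# ---------------------------------------------------------------------------
#
# The joint site marginal sums the discrete latent pair (N_A, N_B) out of
#   Pois(N_A; lam_A) [prod_j Bin(C_ijA; N_A, p_ijA)]
#   * Pois(N_B; lam_B(N_A)) [prod_j Bin(C_ijB; N_B, p_ijB)]
# by truncation at K, in log space.  Terms beyond the integrand's mode decay
# superexponentially, so each sum stops once two consecutive terms fall 60
# log-units below the running maximum — a relative error < ~1e-24 that keeps
# K = 50 affordable inside the sampler.

_TAIL_CUT = 60.0
_LIN_CUT = 1e-26  # linear-space analogue of _TAIL_CUT (e^-60)


@njit(cache=True)
def _one_site_loglik(cA, cB, lpA, lpB0, eps, llamA, llamB0, gamma, K, lgt):
    J = cA.shape[0]
    cAmax = 0
    cBmax = 0
    for j in range(J):
        if cA[j] > cAmax:
            cAmax = cA[j]
        if cB[j] > cBmax:
            cBmax = cB[j]
    if cAmax > K or cBmax > K:
        return np.nan
    if abs(llamA) > 50.0 or abs(llamB0) > 50.0:
        return -np.inf
    lamA = math.exp(llamA)

    pa = np.empty(J)
    lpa = np.empty(J)
    l1pa = np.empty(J)
    lpb = np.empty(J)
    l1pb = np.empty(J)
    for j in range(J):
        x = lpA[j]
        if x > 35.0:
            x = 35.0
        elif x < -35.0:
            x = -35.0
        p = 1.0 / (1.0 + math.exp(-x))
        pa[j] = p
        lpa[j] = math.log(p)
        l1pa[j] = math.log1p(-p)
        y = lpB0[j] + eps * p
        if y > 35.0:
            y = 35.0
        elif y < -35.0:
            y = -35.0
        q = 1.0 / (1.0 + math.exp(-y))
        lpb[j] = math.log(q)
        l1pb[j] = math.log1p(-q)

    # species-B binomial products are shared across the outer sum; fill them
    # lazily (most of 0..K is never visited) and keep scaled linear-space
    # weights wB = exp(qB - shiftB) for the fast inner sum
    qB = np.empty(K + 1)
    wB = np.empty(K + 1)
    filledB = cBmax - 1
    shiftB = -np.inf

    M = -np.inf
    acc = 0.0
    below = 0
    for nA in range(cAmax, K + 1):
        llamB = llamB0 + gamma * nA
        if abs(llamB) > 50.0:
            return -np.inf
        lamB = math.exp(llamB)

        # binomial product for species A at this nA
        bpA = 0.0
        for j in range(J):
            c = cA[j]
            bpA += (lgt[nA + 1] - lgt[c + 1] - lgt[nA - c + 1]
                    + c * lpa[j] + (nA - c) * l1pa[j])
        termA = nA * llamA - lamA - lgt[nA + 1] + bpA

        # inner sum over N_B; linear space when lamB is moderate, log space
        # (overflow-proof) otherwise
        if llamB <= 3.0:
            s_lin = 0.0
            maxterm = 0.0
            pow_l = 1.0
            belowi = 0
            for nB in range(cBmax, K + 1):
                if nB > filledB:
                    q = -lgt[nB + 1]
                    for j in range(J):
                        c = cB[j]
                        q += (lgt[nB + 1] - lgt[c + 1] - lgt[nB - c + 1]
                              + c * lpb[j] + (nB - c) * l1pb[j])
                    qB[nB] = q
                    if q > shiftB:
                        if shiftB > -np.inf:
                            resc = math.exp(shiftB - q)
                            for k in range(cBmax, nB):
                                wB[k] *= resc
                            s_lin *= resc
                            maxterm *= resc
                        shiftB = q
                    wB[nB] = math.exp(q - shiftB)
                    filledB = nB
                t = wB[nB] * pow_l
                if t > maxterm:
                    maxterm = t
                    belowi = 0
                else:
                    if nB > lamB + cBmax and t < maxterm * _LIN_CUT:
                        belowi += 1
                        if belowi >= 2:
                            s_lin += t
                            break
                    else:
                        belowi = 0
                s_lin += t
                pow_l *= lamB
            sB = shiftB + cBmax * llamB - lamB + math.log(s_lin)
        else:
            Mi = -np.inf
            acci = 0.0
            belowi = 0
            for nB in range(cBmax, K + 1):
                if nB > filledB:
                    q = -lgt[nB + 1]
                    for j in range(J):
                        c = cB[j]
                        q += (lgt[nB + 1] - lgt[c + 1] - lgt[nB - c + 1]
                              + c * lpb[j] + (nB - c) * l1pb[j])
                    qB[nB] = q
                    if q > shiftB:
                        if shiftB > -np.inf:
                            resc = math.exp(shiftB - q)
                            for k in range(cBmax, nB):
                                wB[k] *= resc
                        shiftB = q
                    wB[nB] = math.exp(q - shiftB)
                    filledB = nB
                t = nB * llamB - lamB + qB[nB]
                if t > Mi:
                    acci = acci * math.exp(Mi - t) + 1.0
                    Mi = t
                    belowi = 0
                else:
                    acci += math.exp(t - Mi)
                    if nB > lamB + cBmax and t < Mi - _TAIL_CUT:
                        belowi += 1
                        if belowi >= 2:
                            break
                    else:
                        belowi = 0
            sB = Mi + math.log(acci)

        tot = termA + sB
        if tot > M:
            acc = acc * math.exp(M - tot) + 1.0
            M = tot
            below = 0
        else:
            acc += math.exp(tot - M)
            if nA > lamA + cAmax and tot < M - _TAIL_CUT:
                below += 1
                if below >= 2:
                    break
            else:
                below = 0
    return M + math.log(acc)


@njit(cache=True)
def _site_loglik_batch(counts_A, counts_B, lp_A, lp_B0, eps, llam_A, llam_B0,
                       gamma, K, out):
    lgt = np.empty(K + 2)
    lgt[0] = 0.0
    for i in range(1, K + 2):
        lgt[i] = math.lgamma(i)
    for i in range(counts_A.shape[0]):
        out[i] = _one_site_loglik(counts_A[i], counts_B[i], lp_A[i], lp_B0[i],
                                  eps, llam_A[i], llam_B0[i], gamma, K, lgt)


@njit(cache=True)
def _single_species_loglik(counts, lp, llam, K, lgt):
    J = counts.shape[0]
    cmax = 0
    for j in range(J):
        if counts[j] > cmax:
            cmax = counts[j]
    if cmax > K:
        return np.nan
    if abs(llam) > 50.0:
        return -np.inf
    lam = math.exp(llam)
    lp_ = np.empty(J)
    l1p = np.empty(J)
    for j in range(J):
        x = lp[j]
        if x > 35.0:
            x = 35.0
        elif x < -35.0:
            x = -35.0
        p = 1.0 / (1.0 + math.exp(-x))
        lp_[j] = math.log(p)
        l1p[j] = math.log1p(-p)
    M = -np.inf
    acc = 0.0
    below = 0
    for n in range(cmax, K + 1):
        s = n * llam - lam - lgt[n + 1]
        for j in range(J):
            c = counts[j]
            s += lgt[n + 1] - lgt[c + 1] - lgt[n - c + 1] + c * lp_[j] + (n - c) * l1p[j]
        if s > M:
            acc = acc * math.exp(M - s) + 1.0
            M = s
            below = 0
        else:
            acc += math.exp(s - M)
            if n > lam + cmax and s < M - _TAIL_CUT:
                below += 1
                if below >= 2:
                    break
            else:
                below = 0
    return M + math.log(acc)


# ---------------------------------------------------------------------------
# public likelihood API
# ---------------------------------------------------------------------------


def choose_truncation(counts, lam_plausible: float = 10.0, floor: int = 50,
                      cap: int = 5000) -> int:
    """Truncation bound for the latent-abundance sums.

    Takes the largest of: the observed maximum count, the 0.9999 Poisson
    quantile at the largest plausible site rate, and a hard floor.  The
    kernel's early-stopping rule makes a generous K essentially free.
    Counts so large that K would exceed ``cap`` are refused: truncated
    marginalization is the wrong tool at that scale.
    """
    cmax = 0
    for m in counts if isinstance(counts, (list, tuple)) else [counts]:
        cmax = max(cmax, int(np.max(m)) if np.size(m) else 0)
    q = int(math.ceil(stats.poisson.ppf(0.9999, lam_plausible)))
    K = max(floor, cmax, q)
    if K > cap:
        raise ValueError(
            f"required truncation K={K} exceeds cap={cap}; counts this large "
            "are outside the model's intended regime")
    return K


def all_site_logliks(data, covs, params: ModelParams, K: int) -> np.ndarray:
    """Per-site marginal log-likelihoods for every site at once."""
    params = params.with_dims(data.n_sites, data.n_surveys)
    lp_A, lp_B0, llam_A, llam_B0 = build_predictors(params, covs)
    out = np.empty(data.n_sites)
    _site_loglik_batch(data.counts_A, data.counts_B,
                       np.ascontiguousarray(lp_A), np.ascontiguousarray(lp_B0),
                       float(params.epsilon),
                       np.ascontiguousarray(llam_A), np.ascontiguousarray(llam_B0),
                       float(params.gamma), int(K), out)
    if np.any(np.isnan(out)):
        raise ValueError("truncation K is below the maximum observed count")
    return out


def site_marginal_loglik(counts_A_i, counts_B_i, params: ModelParams, covs,
                         site: int, K: int) -> float:
    """Marginal log-likelihood of one site's counts, both latent abundances
    summed out up to K.

    ``counts_A_i``/``counts_B_i`` are that site's count rows; ``site``
    indexes the covariate and random-effect rows to use.  Raises if K is
    below the site's maximum observed count (the likelihood would be 0).
    """
    counts_A_i = np.asarray(counts_A_i, dtype=np.int64).reshape(1, -1)
    counts_B_i = np.asarray(counts_B_i, dtype=np.int64).reshape(1, -1)
    n_surveys = counts_A_i.shape[1]
    params = params.with_dims(covs.n_sites, n_surveys)
    lp_A, lp_B0, llam_A, llam_B0 = build_predictors(params, covs)
    out = np.empty(1)
    _site_loglik_batch(counts_A_i, counts_B_i,
                       np.ascontiguousarray(lp_A[site:site + 1]),
                       np.ascontiguousarray(lp_B0[site:site + 1]),
                       float(params.epsilon),
                       np.ascontiguousarray(llam_A[site:site + 1]),
                       np.ascontiguousarray(llam_B0[site:site + 1]),
                       float(params.gamma), int(K), out)
    if np.isnan(out[0]):
        raise ValueError("truncation K is below the maximum observed count")
    return float(out[0])


def single_species_marginal_loglik(counts_i, logit_p, log_lambda, K: int) -> float:
    """Single-species N-mixture site marginal (no interaction terms).

    Used for the independence reduction: with ``gamma = epsilon = 0`` the
    joint site marginal factorizes into two of these.  For all-zero counts
    and constant p it reduces to the closed form ``lambda((1-p)^J - 1)``.
    """
    counts_i = np.asarray(counts_i, dtype=np.int64).ravel()
    logit_p = np.broadcast_to(np.asarray(logit_p, float), counts_i.shape).copy()
    lgt = np.concatenate([[0.0], [math.lgamma(i) for i in range(1, K + 2)]])
    val = _single_species_loglik(counts_i, logit_p, float(log_lambda), int(K), lgt)
    if np.isnan(val):
        raise ValueError("truncation K is below the maximum observed count")
    return float(val)


def total_log_posterior(data, covs, params: ModelParams, priors: PriorSpec,
                        K: int) -> float:
    """Unnormalized log posterior: site marginals + coefficient priors +
    random-effect log-densities + SD hyperpriors.

    Returns ``-inf`` only when an SD lies outside its Uniform(0, sd_max)
    support.
    """
    params = params.with_dims(data.n_sites, data.n_surveys)
    sigmas = (params.sigma_eta_A, params.sigma_eta_B,
              params.sigma_delta_A, params.sigma_delta_B)
    for s in sigmas:
        if not 0.0 < s < priors.sd_max:
            return -np.inf
    lp = float(np.sum(all_site_logliks(data, covs, params, K)))
    lp += float(np.sum(stats.norm.logpdf(params.coefficients, 0.0, priors.sd_coef)))
    lp += float(np.sum(stats.norm.logpdf(params.eta_A, 0.0, params.sigma_eta_A)))
    lp += float(np.sum(stats.norm.logpdf(params.eta_B, 0.0, params.sigma_eta_B)))
    lp += float(np.sum(stats.norm.logpdf(params.delta_A, 0.0, params.sigma_delta_A)))
    lp += float(np.sum(stats.norm.logpdf(params.delta_B, 0.0, params.sigma_delta_B)))
    lp += 4.0 * (-math.log(priors.sd_max))  # Uniform(0, sd_max) density
    return lp
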
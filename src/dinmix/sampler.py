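"""Metropolis-within-Gibbs sampling and posterior summaries.

Both discrete latent abundances are marginalized analytically (see
:mod:`dinmix.model`), so the sampler only walks the continuous parameters:
the 18 fixed effects (two intercept+slope blocks per process, plus the two
interaction terms), the four random-effect SDs (on the log scale), and the
site-/observation-level random effects themselves.  Random-effect vectors
are updated element-wise in a single vectorized pass — sites are
conditionally independent, so each site's accept/reject uses only its own
marginal likelihood.  Step sizes follow Robbins–Monro adaptation toward a
target acceptance rate during the adaptive phase and are frozen afterwards,
preserving detailed balance for the recorded draws.

Summaries mirror the study's reporting conventions: posterior mean, 90%
highest-density interval, probability of direction (pd), and split-R̂.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .datamodel import collinearity_screen
from .model import _one_site_loglik, choose_truncation, inv_logit

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "run_mcmc",
    "gelman_rubin",
    "hdi",
    "prob_direction",
    "summarize",
    "write_draws",
    "read_draws",
    "CollinearityError",
]

RHAT_THRESHOLD = 1.1


class CollinearityError(RuntimeError):
    """Raised when the covariate screen fails and is not overridden."""


@dataclass(frozen=True)
class MCMCConfig:
    """Chain-protocol settings.

    Defaults follow the full field protocol: 3 chains, a 10,000-iteration
    adaptive phase, 350,000 sampling iterations with the first 50,000
    discarded as burn-in, thinned by 100.  :meth:`desk` gives the reduced
    protocol used for tests and routine synthetic work.
    """

    n_chains: int = 3
    n_adapt: int = 10_000
    n_iter: int = 350_000
    n_burn: int = 50_000
    thin: int = 100
    seed: int = 0
    target_accept: float = 0.3

    def __post_init__(self):
        if self.n_burn >= self.n_iter:
            raise ValueError("n_burn must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for R-hat")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must be in (0, 1)")

    @property
    def n_saved(self) -> int:
        return (self.n_iter - self.n_burn) // self.thin

    @classmethod
    def desk(cls, seed: int = 0, **overrides) -> "MCMCConfig":
        """Reduced protocol: 3 chains × 6,000 iterations (2,000 adaptive),
        burn-in 1,000, thin 5."""
        base = dict(n_chains=3, n_adapt=2_000, n_iter=6_000, n_burn=1_000,
                    thin=5, seed=seed)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def paper(cls, seed: int = 0, **overrides) -> "MCMCConfig":
        """The full field protocol (the class defaults)."""
        return cls(seed=seed, **overrides)


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws of the monitored parameters.

    ``draws`` has shape ``(n_chains, n_saved, n_params)`` in the order given
    by ``param_names``.  Random-effect draws (needed for conditional
    posterior predictive checks) ride along in ``re_draws`` but are not part
    of the monitored set.
    """

    draws: np.ndarray
    param_names: list
    config: MCMCConfig
    seed: int
    re_draws: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.draws.ndim != 3:
            raise ValueError("draws must be (n_chains, n_saved, n_params)")
        if self.draws.shape[2] != len(self.param_names):
            raise ValueError("param name registry does not match draws")
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("draws contain non-finite values")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_saved(self) -> int:
        return self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (n_chains, n_saved)."""
        return self.draws[:, :, self.param_names.index(name)]


# ---------------------------------------------------------------------------
# jitted chain runner
# ---------------------------------------------------------------------------


@njit(cache=True)
def _eval_sites(counts_A, counts_B, Xsite, Xsurv, coef, eta_A, eta_B,
                delta_A, delta_B, K, lgt, out):
    n, J = counts_A.shape
    kv = Xsurv.shape[2]
    ks = Xsite.shape[1]
    oaB = 1 + kv
    obA = 2 * (1 + kv)
    obB = obA + 1 + ks
    og = obB + 1 + ks
    gamma = coef[og]
    eps = coef[og + 1]
    lpA = np.empty(J)
    lpB0 = np.empty(J)
    for i in range(n):
        llamA = coef[obA] + eta_A[i]
        llamB0 = coef[obB] + eta_B[i]
        for k in range(ks):
            llamA += coef[obA + 1 + k] * Xsite[i, k]
            llamB0 += coef[obB + 1 + k] * Xsite[i, k]
        for j in range(J):
            a = coef[0] + delta_A[i, j]
            b = coef[oaB] + delta_B[i, j]
            for k in range(kv):
                a += coef[1 + k] * Xsurv[i, j, k]
                b += coef[oaB + 1 + k] * Xsurv[i, j, k]
            lpA[j] = a
            lpB0[j] = b
        out[i] = _one_site_loglik(counts_A[i], counts_B[i], lpA, lpB0, eps,
                                  llamA, llamB0, gamma, K, lgt)


@njit(cache=True)
def _run_chain(seed, counts_A, counts_B, Xsite, Xsurv, K,
               n_adapt, n_iter, n_burn, thin, target, sd_coef, sd_max,
               out_coef, out_sig, out_eta_A, out_eta_B,
               out_delta_A, out_delta_B):
    np.random.seed(seed)
    n, J = counts_A.shape
    kv = Xsurv.shape[2]
    ks = Xsite.shape[1]
    nc = 2 * (1 + kv) + 2 * (1 + ks) + 2

    lgt = np.empty(K + 2)
    lgt[0] = 0.0
    for i in range(1, K + 2):
        lgt[i] = math.lgamma(i)

    coef = np.empty(nc)
    sig = np.empty(4)
    eta_A = np.zeros(n)
    eta_B = np.zeros(n)
    delta_A = np.zeros((n, J))
    delta_B = np.zeros((n, J))
    cur = np.empty(n)
    new = np.empty(n)

    # initial values: coefficients ~ N(0, 0.5), sigmas ~ U(0.1, 1), REs 0;
    # re-draw on a non-finite posterior
    ok = False
    for _ in range(100):
        for c in range(nc):
            coef[c] = 0.5 * np.random.normal()
        for s in range(4):
            sig[s] = np.random.uniform(0.1, 1.0)
        _eval_sites(counts_A, counts_B, Xsite, Xsurv, coef, eta_A, eta_B,
                    delta_A, delta_B, K, lgt, cur)
        finite = True
        for i in range(n):
            if not np.isfinite(cur[i]):
                finite = False
                break
        if finite:
            ok = True
            break
    if not ok:
        raise ValueError("could not find finite initial values in 100 draws")

    oaB = 1 + kv
    obA = 2 * (1 + kv)
    obB = obA + 1 + ks
    og = obB + 1 + ks

    step_eta = np.full(2, 0.3)
    step_drow = np.full(2, 0.3)
    step_rc = np.full(4, 0.3)      # recentering swaps
    step_scale = np.full(4, 0.3)   # sigma/field joint scale moves
    isd2 = 1.0 / (2.0 * sd_coef * sd_coef)

    # fixed effects move in four adaptive-covariance blocks: the receiver's
    # detection block carries epsilon and its abundance block carries gamma,
    # because each interaction term rides a long posterior ridge with that
    # block's intercept and slopes (epsilon * p_A and gamma * N_A act like
    # extra intercept/covariate terms); an adapted full covariance is what
    # lets the chain slide along those ridges
    dmax = max(2 + kv, 2 + ks)
    bidx = np.zeros((4, dmax), dtype=np.int64)
    blen = np.zeros(4, dtype=np.int64)
    for k in range(1 + kv):
        bidx[0, k] = k
        bidx[1, k] = oaB + k
    bidx[1, 1 + kv] = og + 1      # epsilon joins the alpha_B block
    blen[0] = 1 + kv
    blen[1] = 2 + kv
    for k in range(1 + ks):
        bidx[2, k] = obA + k
        bidx[3, k] = obB + k
    bidx[3, 1 + ks] = og          # gamma joins the beta_B block
    blen[2] = 1 + ks
    blen[3] = 2 + ks

    mu_b = np.zeros((4, dmax))
    m2_b = np.zeros((4, dmax, dmax))
    cnt_b = 0.0
    L_b = np.zeros((4, dmax, dmax))
    for b in range(4):
        for k in range(blen[b]):
            L_b[b, k, k] = 0.1
    ls_b = np.zeros(4)
    zv = np.empty(dmax)
    xv = np.empty(dmax)
    d1 = np.empty(dmax)
    d2v = np.empty(dmax)

    old_coef = np.empty(nc)
    prop_re = np.empty(n)
    prop_d = np.empty((n, J))
    save_idx = 0
    total = n_adapt + n_iter
    for t in range(total):
        adapting = t < n_adapt
        g = (t + 1.0) ** -0.6 if adapting else 0.0

        # fixed effects: four adaptive-covariance random-walk blocks, with a
        # small isotropic mixture component guarding against a degenerate
        # adapted covariance; the receiver's detection block gets a second
        # update per sweep — its ridge with epsilon is the slowest direction
        # in the whole posterior
        for bs in range(5):
            b = bs if bs < 4 else 1
            d_b = blen[b]
            sc = math.exp(ls_b[b])
            for k in range(d_b):
                zv[k] = np.random.normal()
            iso = np.random.uniform(0.0, 1.0) < 0.05
            for k in range(d_b):
                c = bidx[b, k]
                old_coef[c] = coef[c]
                if iso:
                    stp = 0.05 * zv[k]
                else:
                    stp = 0.0
                    for l in range(k + 1):
                        stp += sc * L_b[b, k, l] * zv[l]
                coef[c] = coef[c] + stp
            _eval_sites(counts_A, counts_B, Xsite, Xsurv, coef, eta_A, eta_B,
                        delta_A, delta_B, K, lgt, new)
            d = 0.0
            for k in range(d_b):
                c = bidx[b, k]
                d -= (coef[c] * coef[c] - old_coef[c] * old_coef[c]) * isd2
            for i in range(n):
                d += new[i] - cur[i]
            acc = 0.0
            if d >= 0.0 or np.random.uniform(0.0, 1.0) < math.exp(d):
                acc = 1.0
                for i in range(n):
                    cur[i] = new[i]
            else:
                for k in range(d_b):
                    c = bidx[b, k]
                    coef[c] = old_coef[c]
            if adapting and not iso:
                ls_b[b] += g * (acc - target)

        # accumulate block means/covariances during adaptation (Welford) and
        # refresh the proposal Cholesky factors periodically, frozen after
        if adapting:
            cnt_b += 1.0
            for b in range(4):
                d_b = blen[b]
                for k in range(d_b):
                    xv[k] = coef[bidx[b, k]]
                    d1[k] = xv[k] - mu_b[b, k]
                for k in range(d_b):
                    mu_b[b, k] += d1[k] / cnt_b
                    d2v[k] = xv[k] - mu_b[b, k]
                for k in range(d_b):
                    for l in range(d_b):
                        m2_b[b, k, l] += d1[k] * d2v[l]
            if cnt_b >= 100.0 and int(cnt_b) % 100 == 0:
                for b in range(4):
                    d_b = blen[b]
                    covm = np.empty((d_b, d_b))
                    tr = 0.0
                    for k in range(d_b):
                        for l in range(d_b):
                            covm[k, l] = m2_b[b, k, l] / (cnt_b - 1.0) * (5.6644 / d_b)
                        tr += covm[k, k]
                    reg = 1e-8 + 1e-6 * tr / d_b
                    for k in range(d_b):
                        covm[k, k] += reg
                    Lc = np.linalg.cholesky(covm)
                    for k in range(d_b):
                        for l in range(d_b):
                            L_b[b, k, l] = Lc[k, l]

        # recentering swaps: move an intercept and shift its random-effect
        # field the opposite way; the likelihood is invariant (predictors
        # see only the sum) so the move costs no likelihood evaluation and
        # breaks the intercept/random-effect-mean ridge
        for m in range(4):
            u = step_rc[m] * np.random.normal()
            tot_re = 0.0
            if m == 0:
                i0 = 0
                sg = sig[2]
                for i in range(n):
                    for j in range(J):
                        tot_re += delta_A[i, j]
                mm = n * J
            elif m == 1:
                i0 = oaB
                sg = sig[3]
                for i in range(n):
                    for j in range(J):
                        tot_re += delta_B[i, j]
                mm = n * J
            elif m == 2:
                i0 = obA
                sg = sig[0]
                for i in range(n):
                    tot_re += eta_A[i]
                mm = n
            else:
                i0 = obB
                sg = sig[1]
                for i in range(n):
                    tot_re += eta_B[i]
                mm = n
            a_old = coef[i0]
            a_new = a_old + u
            d = (-(a_new * a_new - a_old * a_old) * isd2
                 - (-2.0 * u * tot_re + mm * u * u) / (2.0 * sg * sg))
            acc = 0.0
            if d >= 0.0 or np.random.uniform(0.0, 1.0) < math.exp(d):
                acc = 1.0
                coef[i0] = a_new
                if m == 0:
                    for i in range(n):
                        for j in range(J):
                            delta_A[i, j] -= u
                elif m == 1:
                    for i in range(n):
                        for j in range(J):
                            delta_B[i, j] -= u
                elif m == 2:
                    for i in range(n):
                        eta_A[i] -= u
                else:
                    for i in range(n):
                        eta_B[i] -= u
            if adapting:
                step_rc[m] *= math.exp(g * (acc - target))

        # random effects: per species, propose each site's eta and its whole
        # delta row jointly; sites are conditionally independent, so one
        # batch evaluation serves every site's own accept/reject
        for which in range(2):
            re = eta_A if which == 0 else eta_B
            de = delta_A if which == 0 else delta_B
            for i in range(n):
                prop_re[i] = re[i] + step_eta[which] * np.random.normal()
                for j in range(J):
                    prop_d[i, j] = de[i, j] + step_drow[which] * np.random.normal()
            if which == 0:
                _eval_sites(counts_A, counts_B, Xsite, Xsurv, coef, prop_re,
                            eta_B, prop_d, delta_B, K, lgt, new)
            else:
                _eval_sites(counts_A, counts_B, Xsite, Xsurv, coef, eta_A,
                            prop_re, delta_A, prop_d, K, lgt, new)
            s2e = 1.0 / (2.0 * sig[which] * sig[which])
            s2d = 1.0 / (2.0 * sig[2 + which] * sig[2 + which])
            nacc = 0
            for i in range(n):
                d = new[i] - cur[i] - (prop_re[i] * prop_re[i] - re[i] * re[i]) * s2e
                for j in range(J):
                    d -= (prop_d[i, j] * prop_d[i, j] - de[i, j] * de[i, j]) * s2d
                if d >= 0.0 or np.random.uniform(0.0, 1.0) < math.exp(d):
                    re[i] = prop_re[i]
                    for j in range(J):
                        de[i, j] = prop_d[i, j]
                    cur[i] = new[i]
                    nacc += 1
            if adapting:
                frac = nacc / n
                step_eta[which] *= math.exp(g * (frac - target))
                step_drow[which] *= math.exp(g * (frac - target))

        # joint scale moves: multiply a random-effect field and its SD by a
        # common factor (one likelihood evaluation, global accept) — this
        # walks along the funnel between sigma and its field, which neither
        # update above can traverse on its own; species A's fields on even
        # iterations, species B's on odd
        for m in range(t % 2, 4, 2):
            z = step_scale[m] * np.random.normal()
            c = math.exp(z)
            acc = 0.0
            if sig[m] * c < sd_max:
                if m < 2:
                    re = eta_A if m == 0 else eta_B
                    for i in range(n):
                        prop_re[i] = c * re[i]
                    if m == 0:
                        _eval_sites(counts_A, counts_B, Xsite, Xsurv, coef,
                                    prop_re, eta_B, delta_A, delta_B, K, lgt, new)
                    else:
                        _eval_sites(counts_A, counts_B, Xsite, Xsurv, coef,
                                    eta_A, prop_re, delta_A, delta_B, K, lgt, new)
                else:
                    de = delta_A if m == 2 else delta_B
                    for i in range(n):
                        for j in range(J):
                            prop_d[i, j] = c * de[i, j]
                    if m == 2:
                        _eval_sites(counts_A, counts_B, Xsite, Xsurv, coef,
                                    eta_A, eta_B, prop_d, delta_B, K, lgt, new)
                    else:
                        _eval_sites(counts_A, counts_B, Xsite, Xsurv, coef,
                                    eta_A, eta_B, delta_A, prop_d, K, lgt, new)
                # prior terms of field and sigma cancel against the Jacobian
                # except for one residual log(c)
                d = z
                for i in range(n):
                    d += new[i] - cur[i]
                if d >= 0.0 or np.random.uniform(0.0, 1.0) < math.exp(d):
                    acc = 1.0
                    sig[m] = sig[m] * c
                    if m == 0:
                        for i in range(n):
                            eta_A[i] = prop_re[i]
                    elif m == 1:
                        for i in range(n):
                            eta_B[i] = prop_re[i]
                    elif m == 2:
                        for i in range(n):
                            for j in range(J):
                                delta_A[i, j] = prop_d[i, j]
                    else:
                        for i in range(n):
                            for j in range(J):
                                delta_B[i, j] = prop_d[i, j]
                    for i in range(n):
                        cur[i] = new[i]
            if adapting:
                step_scale[m] *= math.exp(g * (acc - target))

        # random-effect SDs: exact Gibbs draw from the truncated
        # inverse-gamma conditional (the marginal likelihood depends on
        # sigma only through the effects)
        for s in range(4):
            ssq = 0.0
            if s == 0:
                for i in range(n):
                    ssq += eta_A[i] * eta_A[i]
                m = n
            elif s == 1:
                for i in range(n):
                    ssq += eta_B[i] * eta_B[i]
                m = n
            elif s == 2:
                for i in range(n):
                    for j in range(J):
                        ssq += delta_A[i, j] * delta_A[i, j]
                m = n * J
            else:
                for i in range(n):
                    for j in range(J):
                        ssq += delta_B[i, j] * delta_B[i, j]
                m = n * J
            if m >= 3 and ssq > 1e-12:
                # 1/sigma^2 | field ~ Gamma((m-1)/2, rate ssq/2) truncated to
                # sigma < sd_max; rejection-sample the rarely-binding bound
                shape = (m - 1.0) / 2.0
                lo_tau = 1.0 / (sd_max * sd_max)
                for _try in range(100):
                    tau = np.random.gamma(shape, 2.0 / ssq)
                    if tau > lo_tau:
                        sig[s] = 1.0 / math.sqrt(tau)
                        break
            else:
                old = sig[s]
                prop = old * math.exp(0.3 * np.random.normal())
                if prop < sd_max:
                    d = (-m * math.log(prop) - ssq / (2.0 * prop * prop)
                         + m * math.log(old) + ssq / (2.0 * old * old)
                         + math.log(prop) - math.log(old))
                    if d >= 0.0 or np.random.uniform(0.0, 1.0) < math.exp(d):
                        sig[s] = prop

        # record
        if t >= n_adapt:
            mi = t - n_adapt
            if mi >= n_burn and (mi - n_burn) % thin == thin - 1:
                for c in range(nc):
                    out_coef[save_idx, c] = coef[c]
                for s in range(4):
                    out_sig[save_idx, s] = sig[s]
                out_eta_A[save_idx, :] = eta_A
                out_eta_B[save_idx, :] = eta_B
                out_delta_A[save_idx, :, :] = delta_A
                out_delta_B[save_idx, :, :] = delta_B
                save_idx += 1
    return save_idx


def monitored_names(covs) -> list:
    """Canonical parameter order: detection blocks, abundance blocks,
    interactions, random-effect SDs."""
    names = []
    for sp in ("A", "B"):
        names.append(f"alpha0_{sp}")
        names += [f"alpha_{c}_{sp}" for c in covs.survey_names]
    for sp in ("A", "B"):
        names.append(f"beta0_{sp}")
        names += [f"beta_{c}_{sp}" for c in covs.site_names]
    names += ["gamma", "epsilon",
              "sigma_eta_A", "sigma_eta_B", "sigma_delta_A", "sigma_delta_B"]
    return names


def run_mcmc(data, covs, priors, config: MCMCConfig, K: int | None = None,
             force: bool = False, screen_cutoff: float = 0.7) -> PosteriorDraws:
    """Fit the two-species model by Metropolis-within-Gibbs.

    Refuses to run when the covariate collinearity screen flags any pair
    (override with ``force=True``).  Bit-reproducible given
    ``(config.seed, config, data)``: each chain gets an independent seed
    spawned from the master seed.
    """
    if not covs.standardized:
        raise ValueError("covariates must be standardized before fitting")
    flagged = collinearity_screen(covs, cutoff=screen_cutoff)
    if flagged and not force:
        pairs = ", ".join(f"{a}~{b} (r={r:.2f})" for a, b, r in flagged)
        raise CollinearityError(f"collinear covariate pairs: {pairs}")
    if np.all(data.counts_A == 0) or np.all(data.counts_B == 0):
        warnings.warn("a species has all-zero counts; its intercept is only "
                      "weakly identified", stacklevel=2)
    if K is None:
        K = choose_truncation([data.counts_A, data.counts_B])
    K = int(K)

    n, J = data.counts_A.shape
    names = monitored_names(covs)
    nc = len(names) - 4
    n_saved = config.n_saved
    chain_seeds = np.random.SeedSequence(config.seed).generate_state(config.n_chains)

    draws = np.empty((config.n_chains, n_saved, nc + 4))
    re = {k: np.empty((config.n_chains, n_saved, n)) for k in ("eta_A", "eta_B")}
    re.update({k: np.empty((config.n_chains, n_saved, n, J))
               for k in ("delta_A", "delta_B")})
    Xsite = np.ascontiguousarray(covs.site_covs)
    Xsurv = np.ascontiguousarray(covs.survey_covs)

    for ch in range(config.n_chains):
        oc = np.empty((n_saved, nc))
        osg = np.empty((n_saved, 4))
        oeA = np.empty((n_saved, n))
        oeB = np.empty((n_saved, n))
        odA = np.empty((n_saved, n, J))
        odB = np.empty((n_saved, n, J))
        got = _run_chain(int(chain_seeds[ch]) % (2**32), data.counts_A,
                         data.counts_B, Xsite, Xsurv, K,
                         config.n_adapt, config.n_iter, config.n_burn,
                         config.thin, config.target_accept,
                         priors.sd_coef, priors.sd_max,
                         oc, osg, oeA, oeB, odA, odB)
        assert got == n_saved
        draws[ch, :, :nc] = oc
        draws[ch, :, nc:] = osg
        re["eta_A"][ch] = oeA
        re["eta_B"][ch] = oeB
        re["delta_A"][ch] = odA
        re["delta_B"][ch] = odB

    return PosteriorDraws(draws=draws, param_names=names, config=config,
                          seed=config.seed, re_draws=re)


# ---------------------------------------------------------------------------
# diagnostics & summaries
# ---------------------------------------------------------------------------


def gelman_rubin(draws, param=None) -> float:
    """Split-R̂ convergence diagnostic for one parameter.

    Each chain is split in half, then the usual between/within variance
    ratio is computed over the split chains.  The finite-sample shrink term
    can push the raw ratio marginally below 1, so the statistic is floored
    at 1.  Chains that are exact copies of one another carry no
    between-chain evidence of non-convergence and report exactly 1.0.
    Returns ``+inf`` with a warning when the within-chain variance is zero.
    """
    if isinstance(draws, PosteriorDraws):
        x = draws.get(param)
    else:
        x = np.asarray(draws, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need draws shaped (n_chains >= 2, n_draws)")
    n = x.shape[1]
    if n < 10:
        raise ValueError("need at least 10 saved draws per chain")
    if np.all(x == x[0]) and x[0].var() > 0:
        return 1.0
    half = n // 2
    split = np.concatenate([x[:, :half], x[:, n - half:]], axis=0)
    w = split.var(axis=1, ddof=1).mean()
    if w == 0.0:
        warnings.warn("zero within-chain variance; R-hat undefined", stacklevel=2)
        return float("inf")
    b = half * split.mean(axis=1).var(ddof=1)
    var_plus = (half - 1) / half * w + b / half
    return float(max(1.0, math.sqrt(var_plus / w)))


def hdi(x, mass: float = 0.90) -> tuple:
    """Highest-density interval: the shortest contiguous interval of sorted
    draws holding the requested posterior mass.

    Slides a window spanning ``floor(mass · n)`` order-statistic steps over
    the sorted draws and keeps the first (lowest) shortest window, so ties
    resolve toward the left.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(x, float).ravel())
    n = x.size
    if n < 1:
        raise ValueError("need at least one draw")
    m = int(math.floor(mass * n))
    if m >= n:
        m = n - 1
    if m == 0:
        return (float(x[0]), float(x[0]))
    widths = x[m:] - x[:n - m]
    i = int(np.argmin(widths))
    return (float(x[i]), float(x[i + m]))


def prob_direction(x) -> float:
    """Probability of direction as a percentage in [50, 100]: the share of
    draws on the majority side of zero, zeros counted with the majority."""
    x = np.asarray(x, float).ravel()
    if x.size < 1:
        raise ValueError("need at least one draw")
    pos = np.mean(x > 0)
    neg = np.mean(x < 0)
    zero = np.mean(x == 0)
    return float(100.0 * (max(pos, neg) + zero))


def summarize(draws: PosteriorDraws, mass: float = 0.90) -> pd.DataFrame:
    """Posterior summary table: mean, 90% HDI, pd and split-R̂ per monitored
    parameter, plus the derived mean detection probability
    (``inverse-logit(alpha0)``) and mean site abundance (``exp(beta0)``) for
    each species.  ``converged`` flags parameters with R̂ < 1.1.
    """
    rows = []

    def add_row(name, x2d):
        pooled = x2d.ravel()
        lo, hi = hdi(pooled, mass)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = gelman_rubin(x2d)
        rows.append({"parameter": name, "mean": float(pooled.mean()),
                     "hdi90_lower": lo, "hdi90_upper": hi,
                     "pd": prob_direction(pooled), "rhat": r,
                     "converged": bool(r < RHAT_THRESHOLD)})

    for i, name in enumerate(draws.param_names):
        add_row(name, draws.draws[:, :, i])
    for sp in ("A", "B"):
        add_row(f"mean_p_{sp}", inv_logit(draws.get(f"alpha0_{sp}")))
    for sp in ("A", "B"):
        add_row(f"mean_lambda_{sp}", np.exp(draws.get(f"beta0_{sp}")))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# draws I/O (plain rectangular CSV for external audit)
# ---------------------------------------------------------------------------


def write_draws(draws: PosteriorDraws, path, header_lines=()) -> None:
    n_chains, n_saved, _ = draws.draws.shape
    df = pd.DataFrame(draws.draws.reshape(n_chains * n_saved, -1),
                      columns=draws.param_names)
    df.insert(0, "iteration", np.tile(np.arange(n_saved), n_chains))
    df.insert(0, "chain", np.repeat(np.arange(n_chains), n_saved))
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.10g")


def read_draws(path, config: MCMCConfig | None = None) -> PosteriorDraws:
    """Load a draws CSV written by :func:`write_draws`.

    Random-effect draws are not persisted, so posterior predictive checks on
    re-loaded draws fall back to re-drawing the random effects from their
    fitted SDs.
    """
    df = pd.read_csv(path, comment="#")
    names = [c for c in df.columns if c not in ("chain", "iteration")]
    n_chains = df["chain"].nunique()
    n_saved = df["iteration"].nunique()
    arr = df[names].to_numpy().reshape(n_chains, n_saved, len(names))
    cfg = config or MCMCConfig.desk()
    return PosteriorDraws(draws=arr, param_names=names, config=cfg,
                          seed=cfg.seed)
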
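import numpy as np
import pytest
from scipy import stats

import dinmix as dm
from dinmix.model import build_predictors


def brute_force_site_loglik(cA, cB, params, xs_i, xv_i, etaA, etaB, dA, dB, K):
    """Independent oracle: full double enumeration over (N_A, N_B) on the
    probability scale with scipy pmfs."""
    J = len(cA)
    lamA = np.exp(params.beta_A[0] + xs_i @ params.beta_A[1:] + etaA)
    pA = [dm.detect_prob_A(params.alpha_A, xv_i[j], dA[j]) for j in range(J)]
    pB = [dm.detect_prob_B(params.alpha_B, xv_i[j], pA[j], params.epsilon, dB[j])
          for j in range(J)]
    total = 0.0
    for NA in range(K + 1):
        lamB = np.exp(params.beta_B[0] + xs_i @ params.beta_B[1:]
                      + params.gamma * NA + etaB)
        termA = stats.poisson.pmf(NA, lamA) * np.prod(
            [stats.binom.pmf(cA[j], NA, pA[j]) for j in range(J)])
        if termA == 0.0:
            continue
        sB = sum(stats.poisson.pmf(NB, lamB) * np.prod(
            [stats.binom.pmf(cB[j], NB, pB[j]) for j in range(J)])
            for NB in range(K + 1))
        total += termA * sB
    return np.log(total)


class TestLinkFunctions:
    def test_null_coefficients_give_half(self):
        assert dm.detect_prob_A(np.zeros(4), np.zeros(3)) == pytest.approx(0.5)

    def test_intercept_recovers_mean_p(self):
        a = np.array([float(dm.logit(0.43)), 0, 0, 0])
        assert dm.detect_prob_A(a, np.zeros(3)) == pytest.approx(0.43, abs=1e-12)

    def test_logistic_symmetry(self, rng):
        a = rng.normal(size=3)
        x = rng.normal(size=2)
        p1 = dm.detect_prob_A(a, x)
        p2 = dm.detect_prob_A(-a, x)
        assert p1 + p2 == pytest.approx(1.0, abs=1e-12)

    def test_codetection_reduces_to_plain_when_eps_zero(self, rng):
        a = rng.normal(size=3)
        x = rng.normal(size=2)
        assert dm.detect_prob_B(a, x, p_A=0.7, epsilon=0.0) == pytest.approx(
            dm.detect_prob_A(a, x))

    def test_codetection_at_reported_interaction(self):
        # alpha0 = 0, eps = -3.76, p_A = 0.5 shifts the logit by -1.88
        got = dm.detect_prob_B(np.zeros(4), np.zeros(3), p_A=0.5, epsilon=-3.76)
        assert got == pytest.approx(1 / (1 + np.exp(1.88)), abs=1e-12)

    def test_codetection_monotone_decreasing_in_pA(self):
        lo = dm.detect_prob_B(np.zeros(2), np.zeros(1), p_A=0.9, epsilon=-10.0)
        hi = dm.detect_prob_B(np.zeros(2), np.zeros(1), p_A=0.1, epsilon=-10.0)
        assert lo < hi

    def test_abundance_null_is_one(self):
        assert dm.abundance_rate_A(np.zeros(4), np.zeros(3)) == pytest.approx(1.0)

    def test_abundance_intercept_recovers_mean_lambda(self):
        b = np.array([np.log(0.70), 0, 0, 0])
        assert dm.abundance_rate_A(b, np.zeros(3)) == pytest.approx(0.70, abs=1e-12)

    def test_abundance_increases_with_positive_slope(self):
        b = np.array([0.0, 0.88])
        assert (dm.abundance_rate_A(b, [1.0]) > dm.abundance_rate_A(b, [0.0])
                > dm.abundance_rate_A(b, [-1.0]))

    def test_coabundance_log_linear_in_NA(self):
        b = np.array([np.log(2.10), 0, 0, 0])
        r1 = dm.abundance_rate_B(b, np.zeros(3), N_A=1, gamma=-0.18)
        assert r1 == pytest.approx(2.10 * np.exp(-0.18), abs=1e-12)
        for k in range(4):
            rk = dm.abundance_rate_B(b, np.zeros(3), N_A=k, gamma=-0.18)
            rk1 = dm.abundance_rate_B(b, np.zeros(3), N_A=k + 1, gamma=-0.18)
            assert rk1 / rk == pytest.approx(np.exp(-0.18), abs=1e-12)

    def test_coabundance_independent_of_NA_when_gamma_zero(self):
        b = np.arange(4.0) / 10
        vals = {dm.abundance_rate_B(b, np.ones(3), N_A=k, gamma=0.0)
                for k in range(5)}
        assert len(vals) == 1

    def test_overflowing_predictor_raises(self):
        with pytest.raises(OverflowError):
            dm.abundance_rate_A(np.array([60.0, 0.0]), [0.0])


class TestSiteMarginal:
    def test_matches_brute_force_on_random_instances(self, rng):
        maxerr = 0.0
        for _ in range(30):
            covs = dm.CovariateSet(rng.normal(size=(2, 1)), rng.normal(size=(2, 2, 1)),
                                   ("M",), ("D",), standardized=True)
            p = dm.ModelParams(
                alpha_A=rng.normal(0, 0.8, 2), alpha_B=rng.normal(0, 0.8, 2),
                beta_A=rng.normal(0, 0.8, 2), beta_B=rng.normal(0, 0.8, 2),
                gamma=rng.normal(0, 0.4), epsilon=rng.normal(0, 1.5)).with_dims(2, 2)
            p.eta_A = rng.normal(0, 0.4, 2)
            p.eta_B = rng.normal(0, 0.4, 2)
            p.delta_A = rng.normal(0, 0.4, (2, 2))
            p.delta_B = rng.normal(0, 0.4, (2, 2))
            cA = rng.integers(0, 4, (2, 2))
            cB = rng.integers(0, 4, (2, 2))
            for i in range(2):
                got = dm.site_marginal_loglik(cA[i], cB[i], p, covs, site=i, K=15)
                want = brute_force_site_loglik(
                    cA[i], cB[i], p, covs.site_covs[i], covs.survey_covs[i],
                    p.eta_A[i], p.eta_B[i], p.delta_A[i], p.delta_B[i], K=15)
                maxerr = max(maxerr, abs(got - want))
        assert maxerr < 1e-10

    def test_all_zero_single_species_closed_form(self):
        # log-marginal of all-zero counts is lambda((1-p)^J - 1)
        val = dm.single_species_marginal_loglik([0, 0], dm.logit(0.5), np.log(1.0), 50)
        assert val == pytest.approx(-0.75, abs=1e-12)
        lam, p, J = 2.3, 0.31, 4
        val = dm.single_species_marginal_loglik([0] * J, dm.logit(p), np.log(lam), 80)
        assert val == pytest.approx(lam * ((1 - p) ** J - 1), abs=1e-12)

    def test_factorizes_when_interactions_off(self, tiny_covs, rng):
        p = dm.ModelParams(alpha_A=[0.3, 0.1], alpha_B=[-0.2, 0.4],
                           beta_A=[0.2, -0.1], beta_B=[0.5, 0.2],
                           gamma=0.0, epsilon=0.0).with_dims(2, 2)
        cA, cB = [1, 0], [2, 1]
        joint = dm.site_marginal_loglik(cA, cB, p, tiny_covs, site=0, K=40)
        lp_A, lp_B0, llam_A, llam_B0 = build_predictors(p, tiny_covs)
        sA = dm.single_species_marginal_loglik(cA, lp_A[0], llam_A[0], 40)
        sB = dm.single_species_marginal_loglik(cB, lp_B0[0], llam_B0[0], 40)
        assert joint == pytest.approx(sA + sB, abs=1e-10)

    def test_truncation_stable_doubling_K(self, tiny_covs):
        p = dm.ModelParams(alpha_A=[0.2, 0.0], alpha_B=[0.0, 0.1],
                           beta_A=[np.log(5.0), 0.1], beta_B=[np.log(3.0), -0.2],
                           gamma=0.1, epsilon=-1.0).with_dims(2, 2)
        for K in (50, 60):
            a = dm.site_marginal_loglik([3, 1], [2, 4], p, tiny_covs, site=0, K=K)
            b = dm.site_marginal_loglik([3, 1], [2, 4], p, tiny_covs, site=0, K=2 * K)
            assert abs(a - b) < 1e-8

    def test_K_below_max_count_raises(self, tiny_covs, small_params):
        with pytest.raises(ValueError):
            dm.site_marginal_loglik([5, 1], [0, 0], small_params, tiny_covs,
                                    site=0, K=4)

    def test_site_and_survey_relabeling_invariance(self, rng):
        n, J = 4, 3
        covs = dm.CovariateSet(rng.normal(size=(n, 2)), rng.normal(size=(n, J, 2)),
                               ("a", "b"), ("c", "d"), standardized=True)
        p = dm.ModelParams(alpha_A=rng.normal(size=3), alpha_B=rng.normal(size=3),
                           beta_A=rng.normal(size=3), beta_B=rng.normal(size=3),
                           gamma=-0.2, epsilon=-0.8).with_dims(n, J)
        cA = rng.integers(0, 3, (n, J))
        cB = rng.integers(0, 3, (n, J))
        data = dm.CountData(cA, cB)
        base = np.sum(dm.all_site_logliks(data, covs, p, K=30))

        perm_s = rng.permutation(n)
        perm_j = rng.permutation(J)
        covs2 = dm.CovariateSet(covs.site_covs[perm_s],
                                covs.survey_covs[perm_s][:, perm_j, :],
                                ("a", "b"), ("c", "d"), standardized=True)
        data2 = dm.CountData(cA[perm_s][:, perm_j], cB[perm_s][:, perm_j])
        relab = np.sum(dm.all_site_logliks(data2, covs2, p, K=30))
        assert relab == pytest.approx(base, abs=1e-10)

    def test_codetection_suppresses_B_when_pA_high(self):
        # marginal P(C_B > 0) at a cell is non-increasing in p_A when
        # epsilon < 0, all else fixed (enumerated over the latent pair)
        lam_A, gamma, eps, K = 1.2, -0.18, -6.0, 60
        prev = 1.0
        for a0A in (-2.0, 0.0, 2.0):  # increasing p_A
            p_A = dm.detect_prob_A(np.array([a0A, 0.0]), [0.0])
            p_B = dm.detect_prob_B(np.array([0.0, 0.0]), [0.0], p_A, eps)
            p_nonzero = 0.0
            for NA in range(K + 1):
                lam_B = dm.abundance_rate_B(np.array([np.log(2.0), 0.0]),
                                            [0.0], NA, gamma)
                pz = sum(stats.poisson.pmf(NB, lam_B) * (1 - p_B) ** NB
                         for NB in range(K + 1))
                p_nonzero += stats.poisson.pmf(NA, lam_A) * (1 - pz)
            assert p_nonzero <= prev + 1e-12
            prev = p_nonzero


class TestTotalLogPosterior:
    def _setup(self, rng, n=2, J=2):
        covs = dm.CovariateSet(rng.normal(size=(n, 1)), rng.normal(size=(n, J, 1)),
                               ("M",), ("D",), standardized=True)
        p = dm.ModelParams(alpha_A=rng.normal(size=2), alpha_B=rng.normal(size=2),
                           beta_A=rng.normal(size=2), beta_B=rng.normal(size=2),
                           gamma=0.1, epsilon=-0.5,
                           sigma_eta_A=0.4, sigma_eta_B=0.6,
                           sigma_delta_A=0.3, sigma_delta_B=0.8).with_dims(n, J)
        p.eta_A = rng.normal(0, 0.3, n)
        p.eta_B = rng.normal(0, 0.3, n)
        p.delta_A = rng.normal(0, 0.3, (n, J))
        p.delta_B = rng.normal(0, 0.3, (n, J))
        data = dm.CountData(rng.integers(0, 3, (n, J)), rng.integers(0, 3, (n, J)))
        return data, covs, p

    def test_matches_term_by_term_reassembly(self, rng):
        data, covs, p = self._setup(rng)
        priors = dm.PriorSpec(sd_coef=10.0, sd_max=5.0)
        got = dm.total_log_posterior(data, covs, p, priors, K=30)
        want = 0.0
        for i in range(2):
            want += brute_force_site_loglik(
                data.counts_A[i], data.counts_B[i], p, covs.site_covs[i],
                covs.survey_covs[i], p.eta_A[i], p.eta_B[i],
                p.delta_A[i], p.delta_B[i], K=30)
        for v in p.coefficients:
            want += stats.norm.logpdf(v, 0, 10.0)
        want += stats.norm.logpdf(p.eta_A, 0, 0.4).sum()
        want += stats.norm.logpdf(p.eta_B, 0, 0.6).sum()
        want += stats.norm.logpdf(p.delta_A, 0, 0.3).sum()
        want += stats.norm.logpdf(p.delta_B, 0, 0.8).sum()
        want += 4 * np.log(1 / 5.0)
        assert got == pytest.approx(want, abs=1e-8)

    def test_adding_a_site_adds_its_terms(self, rng):
        data, covs, p = self._setup(rng, n=3)
        priors = dm.PriorSpec()
        full = dm.total_log_posterior(data, covs, p, priors, K=30)

        def drop_last(x):
            return x[:-1]

        data2 = dm.CountData(data.counts_A[:-1], data.counts_B[:-1])
        covs2 = dm.CovariateSet(covs.site_covs[:-1], covs.survey_covs[:-1],
                                covs.site_names, covs.survey_names,
                                standardized=True)
        import dataclasses
        p2 = dataclasses.replace(p, eta_A=drop_last(p.eta_A), eta_B=drop_last(p.eta_B),
                                 delta_A=p.delta_A[:-1], delta_B=p.delta_B[:-1])
        part = dm.total_log_posterior(data2, covs2, p2, priors, K=30)
        site_term = dm.all_site_logliks(data, covs, p, K=30)[-1]
        re_terms = (stats.norm.logpdf(p.eta_A[-1], 0, p.sigma_eta_A)
                    + stats.norm.logpdf(p.eta_B[-1], 0, p.sigma_eta_B)
                    + stats.norm.logpdf(p.delta_A[-1], 0, p.sigma_delta_A).sum()
                    + stats.norm.logpdf(p.delta_B[-1], 0, p.sigma_delta_B).sum())
        assert full == pytest.approx(part + site_term + re_terms, abs=1e-8)

    def test_doubling_sd_coef_changes_only_coef_terms(self, rng):
        data, covs, p = self._setup(rng)
        a = dm.total_log_posterior(data, covs, p, dm.PriorSpec(sd_coef=10), K=30)
        b = dm.total_log_posterior(data, covs, p, dm.PriorSpec(sd_coef=20), K=30)
        expected_delta = (stats.norm.logpdf(p.coefficients, 0, 20).sum()
                          - stats.norm.logpdf(p.coefficients, 0, 10).sum())
        assert b - a == pytest.approx(expected_delta, abs=1e-10)

    def test_sigma_outside_support_gives_neg_inf(self, rng):
        data, covs, p = self._setup(rng)
        p.sigma_eta_A = 7.0  # beyond Uniform(0, 5)
        assert dm.total_log_posterior(data, covs, p, dm.PriorSpec(), K=30) == -np.inf


def test_choose_truncation_rules():
    assert dm.choose_truncation(np.zeros((3, 2), dtype=int)) == 50
    assert dm.choose_truncation(np.full((2, 2), 80)) == 80
    assert dm.choose_truncation(np.zeros((2, 2), dtype=int),
                                lam_plausible=40.0) > 50
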
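import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dinmix as dm
from dinmix.sampler import monitored_names


class TestConfig:
    def test_paper_protocol_defaults(self):
        cfg = dm.MCMCConfig()
        assert (cfg.n_chains, cfg.n_adapt, cfg.n_iter, cfg.n_burn, cfg.thin) == \
            (3, 10_000, 350_000, 50_000, 100)
        assert cfg.n_saved == 3000

    def test_desk_bookkeeping(self):
        cfg = dm.MCMCConfig.desk()
        assert cfg.n_saved == (cfg.n_iter - cfg.n_burn) // cfg.thin == 1000

    @pytest.mark.parametrize("kwargs", [
        dict(n_burn=6000, n_iter=6000), dict(thin=0), dict(n_chains=1)])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            dm.MCMCConfig.desk(**kwargs)


class TestRunMcmc:
    def test_same_seed_identical_draws(self, quick_fit):
        sim, draws = quick_fit
        cfg = dm.MCMCConfig.desk(seed=5, n_adapt=1000, n_iter=3000,
                                 n_burn=500, thin=5)
        again = dm.run_mcmc(sim.data, sim.covs, dm.PriorSpec(), cfg, force=True)
        np.testing.assert_array_equal(draws.draws, again.draws)

    def test_saved_draw_count_and_names(self, quick_fit):
        _, draws = quick_fit
        assert draws.draws.shape == (3, 500, 22)
        assert draws.param_names[:2] == ["alpha0_A", "alpha_DAY_A"]
        assert draws.param_names[-6:] == ["gamma", "epsilon", "sigma_eta_A",
                                          "sigma_eta_B", "sigma_delta_A",
                                          "sigma_delta_B"]

    def test_unstandardized_covariates_rejected(self, rng):
        design = dm.DesignSpec(n_sites=4, n_surveys=2)
        sim = dm.simulate(design, dm.neutral_truth(), seed=0)
        raw = dm.destandardize(sim.covs)
        with pytest.raises(ValueError, match="standardized"):
            dm.run_mcmc(sim.data, raw, dm.PriorSpec(), dm.MCMCConfig.desk())

    def test_collinear_covariates_block_fit(self, rng):
        x = rng.normal(size=6)
        covs = dm.CovariateSet(np.column_stack([x, x]), rng.normal(size=(6, 2, 1)),
                               ("a", "b"), ("c",), standardized=True)
        data = dm.CountData(np.zeros((6, 2), int), np.zeros((6, 2), int))
        with pytest.raises(dm.CollinearityError, match="a~b"):
            dm.run_mcmc(data, covs, dm.PriorSpec(), dm.MCMCConfig.desk())


class TestCalibration:
    def test_sbc_rank_uniformity(self):
        """Simulation-based calibration on a reduced design: the rank of
        each generating parameter among its posterior draws should be
        uniform when truths are drawn from the fitting prior."""
        import dataclasses
        from scipy import stats as sps

        n_reps, sd = 40, 0.7
        priors = dm.PriorSpec(sd_coef=sd, sd_max=0.75)
        design = dm.DesignSpec(n_sites=10, n_surveys=2, site_cov_names=("X",),
                               survey_cov_names=("W",), survey_site_jitter=1.0)
        cfg = dm.MCMCConfig.desk(n_chains=2, n_adapt=1000, n_iter=2500,
                                 n_burn=500, thin=4)
        ss = np.random.SeedSequence(321).generate_state(3 * n_reps)
        ranks = {}
        kept = 0
        for r in range(n_reps):
            trng = np.random.default_rng(int(ss[3 * r]) % 2**31)
            truth = dm.ModelParams(
                alpha_A=trng.normal(0, sd, 2), alpha_B=trng.normal(0, sd, 2),
                beta_A=trng.normal(0, sd, 2), beta_B=trng.normal(0, sd, 2),
                gamma=trng.normal(0, sd), epsilon=trng.normal(0, sd),
                sigma_eta_A=trng.uniform(1e-3, 0.75),
                sigma_eta_B=trng.uniform(1e-3, 0.75),
                sigma_delta_A=trng.uniform(1e-3, 0.75),
                sigma_delta_B=trng.uniform(1e-3, 0.75))
            sim = dm.simulate(design, truth, int(ss[3 * r + 1]) % 2**31)
            if max(sim.data.counts_A.max(), sim.data.counts_B.max()) > 60:
                continue  # explosive co-abundance cascade; out of regime
            cfg_r = dataclasses.replace(cfg, seed=int(ss[3 * r + 2]) % 2**31)
            draws = dm.run_mcmc(sim.data, sim.covs, priors, cfg_r, force=True)
            td = dm.truth_as_dict(sim.truth, sim.covs)
            for nm in draws.param_names:
                ranks.setdefault(nm, []).append(
                    int(np.sum(draws.get(nm).ravel() < td[nm])))
            kept += 1
        assert kept >= 30
        n_draws = 2 * cfg.n_saved
        n_params = len(ranks)
        for nm, rk in ranks.items():
            h = np.histogram(rk, bins=5, range=(0, n_draws + 1))[0]
            chi2 = ((h - kept / 5) ** 2 / (kept / 5)).sum()
            p = 1 - sps.chi2.cdf(chi2, 4)
            # Bonferroni across the monitored parameters
            assert p > 0.01 / n_params, f"{nm}: rank chi2 p = {p:.2g}"


class TestGelmanRubin:
    def test_identical_chains_give_one(self, rng):
        x = rng.normal(size=1000)
        chains = np.vstack([x, x, x])
        assert dm.gelman_rubin(chains) == pytest.approx(1.0, abs=1e-6)

    def test_separated_chains_flagged(self, rng):
        chains = np.vstack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert dm.gelman_rubin(chains) > 1.1

    def test_zero_variance_warns_inf(self):
        with pytest.warns(UserWarning):
            r = dm.gelman_rubin(np.ones((2, 100)))
        assert r == np.inf

    def test_matches_two_pass_reference(self, rng):
        def reference_split_rhat(x):
            """Textbook two-pass split-R̂: explicit loops, no shortcuts."""
            m, n = x.shape
            half = n // 2
            chains = []
            for c in range(m):
                chains.append(list(x[c, :half]))
                chains.append(list(x[c, n - half:]))
            means = [sum(ch) / half for ch in chains]
            within = []
            for ch, mu in zip(chains, means):
                within.append(sum((v - mu) ** 2 for v in ch) / (half - 1))
            w = sum(within) / len(within)
            grand = sum(means) / len(means)
            b = half * sum((mu - grand) ** 2 for mu in means) / (len(means) - 1)
            var_plus = (half - 1) / half * w + b / half
            return max(1.0, (var_plus / w) ** 0.5)

        for trial in range(5):
            x = rng.normal(size=(3, 101)) + rng.normal(size=(3, 1))
            assert dm.gelman_rubin(x) == pytest.approx(
                reference_split_rhat(x), abs=1e-10)


class TestHdi:
    def test_uniform_grid_width(self):
        lo, hi = dm.hdi(np.arange(1, 101), 0.90)
        assert (lo, hi) == (1, 91)
        assert hi - lo == 90

    def test_point_mass_zero_width(self):
        lo, hi = dm.hdi(np.full(50, 3.3), 0.90)
        assert lo == hi == 3.3

    def test_close_to_quantile_interval_for_symmetric_sample(self, rng):
        x = rng.normal(size=100_000)
        lo, hi = dm.hdi(x, 0.90)
        qlo, qhi = np.quantile(x, [0.05, 0.95])
        assert lo == pytest.approx(qlo, abs=0.05)
        assert hi == pytest.approx(qhi, abs=0.05)

    def test_agrees_with_arviz(self, rng):
        az = pytest.importorskip("arviz")
        for _ in range(5):
            x = rng.gamma(2.0, 1.0, size=2000)
            lo, hi = dm.hdi(x, 0.90)
            ref = az.hdi(x, hdi_prob=0.90)
            assert lo == pytest.approx(ref[0], abs=1e-12)
            assert hi == pytest.approx(ref[1], abs=1e-12)

    def test_invalid_mass_rejected(self):
        with pytest.raises(ValueError):
            dm.hdi(np.arange(30), 1.2)

    @given(st.integers(0, 2**31 - 1), st.floats(0.5, 0.99))
    def test_contains_at_least_requested_mass(self, seed, mass):
        x = np.random.default_rng(seed).normal(size=200)
        lo, hi = dm.hdi(x, mass)
        assert lo <= hi
        assert np.mean((x >= lo) & (x <= hi)) >= mass


class TestProbDirection:
    def test_unanimous(self):
        assert dm.prob_direction([-3.0, -1.0, -0.5]) == 100.0

    def test_split_half(self):
        assert dm.prob_direction([-1, -2, 1, 2]) == 50.0

    def test_constructed_897_of_1000(self, rng):
        x = np.concatenate([-rng.uniform(0.1, 2, 897), rng.uniform(0.1, 2, 103)])
        assert dm.prob_direction(x) == pytest.approx(89.7)

    def test_zeros_count_with_majority(self):
        assert dm.prob_direction([0.0, 0.0, -1.0]) == 100.0

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=100))
    def test_range_and_sign_flip_invariance(self, xs):
        x = np.asarray(xs)
        pd_val = dm.prob_direction(x)
        assert 50.0 <= pd_val <= 100.0
        assert dm.prob_direction(-x) == pd_val


class TestSummarize:
    def test_point_mass_rows(self):
        names = monitored_names(
            dm.CovariateSet(np.zeros((2, 3)), np.zeros((2, 2, 3)),
                            ("MOIST", "INSOL", "TPI"), ("DAY", "TEMP", "RAIN")))
        arr = np.full((2, 50, 22), 1.7)
        draws = dm.PosteriorDraws(draws=arr, param_names=names,
                                  config=dm.MCMCConfig.desk(), seed=0)
        summ = dm.summarize(draws)
        row = summ[summ.parameter == "gamma"].iloc[0]
        assert row["mean"] == pytest.approx(1.7, abs=1e-12)
        assert row["hdi90_lower"] == row["hdi90_upper"] == 1.7
        assert row["pd"] == 100.0

    def test_full_monitored_row_set(self, quick_fit):
        _, draws = quick_fit
        summ = dm.summarize(draws)
        expected = set(draws.param_names) | {
            "mean_p_A", "mean_p_B", "mean_lambda_A", "mean_lambda_B"}
        assert set(summ.parameter) == expected
        assert len(summ) == 26
        # derived rows are transforms of the intercept draws
        a0 = draws.get("alpha0_A").ravel()
        assert summ.set_index("parameter").loc["mean_p_A", "mean"] == \
            pytest.approx(dm.inv_logit(a0).mean())

    def test_rhat_flag_column(self, quick_fit):
        _, draws = quick_fit
        summ = dm.summarize(draws)
        assert ((summ.rhat < 1.1) == summ.converged).all()

    def test_csv_round_trip_six_significant_digits(self, quick_fit, tmp_path):
        _, draws = quick_fit
        summ = dm.summarize(draws)
        f = tmp_path / "summary.csv"
        summ.to_csv(f, index=False, float_format="%.6g")
        back = pd.read_csv(f)
        for col in ("mean", "hdi90_lower", "hdi90_upper", "pd", "rhat"):
            np.testing.assert_allclose(back[col], summ[col], rtol=1e-5)


class TestDrawsIO:
    def test_write_read_round_trip(self, quick_fit, tmp_path):
        _, draws = quick_fit
        f = tmp_path / "draws.csv"
        dm.write_draws(draws, f, header_lines=["test"])
        back = dm.read_draws(f, config=draws.config)
        assert back.param_names == draws.param_names
        np.testing.assert_allclose(back.draws, draws.draws, rtol=1e-9)

    def test_header_comment_present(self, quick_fit, tmp_path):
        _, draws = quick_fit
        f = tmp_path / "draws.csv"
        dm.write_draws(draws, f, header_lines=["dinmix test", "seed=5"])
        text = f.read_text()
        assert text.startswith("# dinmix test\n# seed=5\n")
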
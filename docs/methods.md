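# Methods

## Model

`dinmix` fits a two-species stacked binomial N-mixture model with
directional interaction terms on both the state and the observation
process. For sites `i = 1..M` and repeat surveys `j = 1..J` within a closed
season, with species A the "donor" (in the motivating system: the larger,
competitively dominant salamander) and species B the "receiver":

    N_iA ~ Poisson(lambda_iA)
    N_iB ~ Poisson(lambda_iB)
    C_ijA | N_iA ~ Binomial(N_iA, p_ijA)
    C_ijB | N_iB ~ Binomial(N_iB, p_ijB)

    logit(p_ijA) = alpha0_A + alpha_A' x_ij                     + delta_ijA
    logit(p_ijB) = alpha0_B + alpha_B' x_ij + epsilon * p_ijA   + delta_ijB
    log(lambda_iA) = beta0_A + beta_A' z_i                      + eta_iA
    log(lambda_iB) = beta0_B + beta_B' z_i  + gamma * N_iA      + eta_iB

where `x_ij` are survey-level covariates (day of year, temperature,
antecedent rain in the motivating design), `z_i` site-level covariates
(soil moisture, insolation, topographic position), `delta` observation-level
and `eta` site-level normal random effects (`delta_ijs ~ N(0,
sigma_delta_s)`, `eta_is ~ N(0, sigma_eta_s)`, one SD per species per
level) absorbing extra-binomial and extra-Poisson dispersion.

The two interaction terms carry the scientific content:

* `gamma` multiplies the donor's **raw latent integer abundance** `N_iA`.
  A negative `gamma` means plots holding many donors hold fewer receivers
  after habitat adjustment — spatial segregation, the signature of
  exploitative competition.
* `epsilon` multiplies the donor's **detection probability on the
  probability scale** `p_ijA` (so `epsilon = -3.76` means a shift of up to
  -3.76 logits as `p_A` goes from 0 to 1). Detection probability proxies
  surface activity, so a negative `epsilon` means the receiver is less
  active when the donor is active — temporal niche partitioning, the
  signature of interference competition.

Both scale choices follow the stacked-model formulation this model family
uses: the latent abundance and the detection probability enter the other
species' predictors directly "as covariates", unstandardized.

Covariates are z-scored (sample SD, `n-1` denominator) before entering the
predictors; site covariates over sites, survey covariates over all
site × survey cells jointly since each feeds a single linear predictor.
A Pearson screen refuses to fit when any covariate pair has `|r| >= 0.7`
(equality excludes, since inclusion requires `r < 0.7`); the screen can be
overridden deliberately.

### Priors

Normal(0, 10) on every fixed effect including `gamma` and `epsilon`;
Uniform(0, 5) on the four random-effect SDs. Both scales are configurable
(`PriorSpec`). These are conventional weakly-informative choices for this
model family; the random-effect SD hyperpriors are a package decision, not
a reported quantity.

## Marginalized likelihood

The discrete latent pair `(N_iA, N_iB)` is summed out of each site's
likelihood by truncation at `K`:

    L_i = sum_{N_A} Pois(N_A; lam_A) [prod_j Bin(C_ijA; N_A, p_ijA)]
          * sum_{N_B} Pois(N_B; lam_B(N_A)) [prod_j Bin(C_ijB; N_B, p_ijB)]

computed in log space. The default `K` is the largest of 50, the observed
maximum count, and the 0.9999 Poisson quantile at a plausible ceiling rate
(`lam_plausible = 10`); a required `K` above 5,000 is refused because
truncated marginalization is the wrong tool at that scale. Inside the
kernel each sum stops once two consecutive terms past the integrand's mode
fall 60 log-units (~1e-26 relative) below the running maximum, so a
generous `K` costs almost nothing; doubling `K` changes site
log-likelihoods by far less than 1e-8 (tested). The inner sum runs on a
scaled linear scale (weights `exp(q_n - max q)`) for moderate rates and
falls back to log-space accumulation when `log lambda_B > 3` to rule out
overflow. Binomial-product terms are filled lazily, only as far as the
sums actually reach. Site marginals agree with brute-force enumeration
over `(N_A, N_B)` to ~1e-14 on randomized tiny instances (tested at 1e-10
tolerance).

Marginalizing the latent abundances — rather than sampling them by data
augmentation — targets the identical posterior over the continuous
parameters while mixing faster and making diagnostics simpler.

## Sampler

Metropolis-within-Gibbs over the continuous parameters, jit-compiled
(numba). One iteration sweeps:

1. the fixed effects in four **adaptive-covariance random-walk blocks**
   (Haario-style): `[alpha_A]`, `[alpha_B, epsilon]`, `[beta_A]`,
   `[beta_B, gamma]`. Each interaction term lives in the block whose
   predictors it rides: `epsilon * p_A` acts like an extra
   intercept/covariate in the receiver's detection predictor and
   `gamma * N_A` in its abundance predictor, producing long posterior
   ridges that only a full-covariance proposal traverses. Block means and
   covariances accumulate by Welford updates during the adaptive phase;
   the proposal Cholesky (scaled `2.38^2/d`) refreshes every 100
   adaptation iterations and freezes afterwards. A 5% isotropic mixture
   component guards against degenerate adapted covariances. The
   receiver's detection block is updated twice per sweep — its ridge with
   `epsilon` is the slowest direction in the posterior;
2. two likelihood-free **recentering swaps** per process: an intercept
   shift `u` paired with the opposite shift of its random-effect field
   leaves every predictor unchanged, so only the priors enter the accept
   ratio — this breaks the intercept/random-effect-mean ridge;
3. per-site random effects: each site's `eta_i` and whole `delta_i·` row
   proposed jointly; one batch likelihood evaluation serves every site's
   own accept/reject because sites are conditionally independent;
4. joint **scale moves** (alternating species by iteration parity):
   multiply a random-effect field and its SD by a common factor, with the
   single residual `log c` term after prior/Jacobian cancellation — this
   traverses the funnel between `sigma` and its field;
5. exact Gibbs draws of each `sigma` from its truncated inverse-gamma
   conditional (`1/sigma^2 | field ~ Gamma((m-1)/2, rate ssq/2)` truncated
   to `sigma < sd_max`, by rejection).

Scalar step sizes and the block proposal scales follow Robbins–Monro
adaptation (`gain t^-0.6`) toward 0.3 acceptance during the adaptive
phase only and are frozen afterwards, so the recorded phase is a
fixed-kernel chain. Initial values: coefficients
~ N(0, 0.5), SDs ~ U(0.1, 1), random effects 0, re-drawn (up to 100 times)
if the posterior is non-finite. Chains are seeded independently from one
master seed; runs are bit-reproducible given (seed, config, data).

Correctness was validated by simulation-based calibration: truths drawn
from a narrowed prior (coefficient SD 0.7, SD cap 0.75 — the full
Normal(0,10) prior generates astronomically explosive co-abundance
cascades when `gamma > 0`, which no truncated sum should be asked to
marginalize), 10 sites × 2 surveys, one covariate per level; the rank of
each true parameter among posterior draws is checked for uniformity. The
test suite runs a reduced replicate count; a 200-replicate run was used
during development.

### Protocols

`MCMCConfig` defaults to the full field protocol — 3 chains, 10,000
adaptive iterations, 350,000 sampling iterations, 50,000 burn-in, thin 100
(3,000 saved draws per chain). `MCMCConfig.desk()` is the working default
everywhere else: 3 chains × 6,000 iterations (2,000 adaptive), burn-in
1,000, thin 5 (1,000 saved per chain). The desk protocol is what the test
suite, the acceptance script and the analysis drivers use; the full
protocol is ~60× longer and available via `--protocol paper`.

## Posterior summaries

* **90% HDI**: shortest contiguous interval of sorted draws spanning
  `floor(0.9 n)` order-statistic steps; ties resolve to the lowest window.
  (On draws `1..100` this gives `[1, 91]`, width 90.)
* **pd (probability of direction)**: percentage of draws on the majority
  side of zero, zeros counted with the majority; range [50, 100].
* **split-R̂**: each chain halved, then the classic between/within variance
  ratio over the split chains. The finite-sample shrink term `(n-1)/n` can
  push the raw ratio a hair below 1, so the statistic is floored at 1:
  duplicated chains report exactly 1.0. Convergence rule: R̂ < 1.1 on every
  monitored parameter.
* Summaries also report the derived mean detection probability
  `inverse-logit(alpha0)` and mean site abundance `exp(beta0)` per species,
  each summarized from the transformed draws.

## Posterior predictive checks

Chi-square discrepancy `T = sum_ij (C_ij - E_ij)^2 / (E_ij + c)` with
stabilizer `c = 0.5`, summed over site × survey cells (both `c` and the
cell definition are arguments). The expected count is the marginal mean
`E_ij = lambda_i p_ij`; for the receiver the donor's latent abundance is
integrated out analytically, `E[exp(gamma N_A)] = exp(lambda_A (e^gamma -
1))` under the Poisson. For each retained draw a full generative replicate
(latent abundances and counts) is simulated and `p = Pr(T_rep > T_obs)`
(strict inequality; ties shrink p).

Conditioning on the random effects has two variants. When the fitted
random-effect draws are available (draws straight from `run_mcmc`) the
check conditions on them — the classic conditional check, whose p-values
sit comfortably mid-interval on well-specified data. For draws re-loaded
from CSV (where random effects are not persisted) the check is **mixed**:
random effects are redrawn from their drawn SDs, with the expectation
surface and the replicate receiving *independent* draws so observed and
replicated counts face the expectation symmetrically — sharing one redrawn
set between expectation and replicate would make the p-value
anti-conservative. `condition_on_random_effects` overrides the automatic
choice.

A finding worth knowing when using the check: if data containing a single
grossly corrupted cell are *refitted*, the observation- and site-level
random effects absorb the outlier entirely (`eta` raises that site's
rate, `delta` that cell's detection), the random-effect SD posteriors
inflate, and every chi-square PPC variant then correctly reports that the
refitted model fits — the model class is simply flexible enough to
accommodate one wild cell. Outlier screening with this check therefore
means scoring suspect data against an existing fit (as the `ppc` CLI
subcommand does), not refitting first.

## Synthetic data

The generator mirrors the generative model exactly on the study's design
(26 plots × 3 surveys by default): covariates are drawn standard normal
and then z-scored, so generating truths live on the fitted scale; random
effects, latent abundances and counts follow the model equations;
simulated counts can never exceed their latent abundance. The default
generating truth is the study's posterior point-estimate column
(intercepts back-transformed from mean p = 0.43/0.32 and mean
lambda = 0.70/2.10; `gamma = -0.18`, `epsilon = -3.76`); the
random-effect SDs default to 0.5, an invented value — the study reports
none.

Survey covariates are occasion-level weather/date variables, so by default
each survey occasion gets one value shared by all sites;
`survey_site_jitter` adds per-site variation. A consequence of the shared
default worth knowing: with only three occasions, two survey covariates
are frequently near-collinear by chance (three points determine r), and
roughly half of such simulated designs fail the package's own
collinearity screen. The validation experiments therefore draw survey
covariates per cell (`survey_site_jitter = 1`), except the 130-site
sign-detection experiment, which keeps the occasion-shared design to stay
close to the study's layout (the recovery harness overrides the screen,
since the generator's covariates are independent by construction). A
`study_like` preset induces a negative moisture/topography correlation
(~-0.4, below the screen).

What the generator does **not** emulate: spatial autocorrelation between
plots (the study's 20 m minimum spacing is treated as independence, as the
model itself assumes), non-Gaussian covariate distributions, and any
observation process beyond binomial thinning. Passing recovery tests on
these data therefore validates the inference machinery, not the field
realism of the model.

## Validation experiment sizes

Chosen once as the package's working conditions:

* likelihood oracle: 100 random tiny instances (≤3 sites, 2 surveys,
  counts ≤3, K = 15) against brute-force enumeration, tolerance 1e-10;
* null recovery: 20 replicates, 40 sites × 3 surveys, neutral truth
  (all fixed effects 0, sigma = 0.5), desk protocol; per-fixed-effect 90%
  HDI coverage ≥ 0.70 (binomial tolerance around 0.90 at n = 20) and
  |bias| < half a prior SD;
* sign detection: 10 replicates at the study-estimate truth, 130 sites,
  3 × 4,000 iterations (burn 1,000, thin 3), scoring how often the
  posterior mean of epsilon is negative and pd exceeds 85%;
* PPC calibration: 20 replicates, 26 sites, informative truth
  (p ≈ 0.6, lambda = 2), 3 × 3,000 iterations; p-values inside
  (0.05, 0.95) in ≥ 18/20, and p < 0.05 when a copy of one dataset with a
  cell corrupted by +20 is scored against the clean fit;
* convergence: R̂ < 1.1 on all 22 monitored parameters of one informative
  40-site desk-protocol fit.

## Known limitations

* With `gamma > 0` the co-abundance cascade `lambda_B = exp(... + gamma
  N_A)` has explosive tails; the truncation guard refuses datasets whose
  counts would need `K > 5,000`. The directional formulation is meant for
  (and numerically safest in) the competitive, `gamma <= 0`-leaning regime.
* `sigma_delta` is only weakly identified from sparse 0/1 counts; its
  posterior can sit far from a generating value while the fixed effects
  remain well calibrated. This is a property of the model at these sample
  sizes, not of the sampler.
* The co-detection term `epsilon` is intrinsically weakly identified:
  `epsilon * p_A(x)` is nearly collinear with the receiver's own
  detection predictor (which uses the same covariates), and the
  cell-level part of `p_A` (its `delta_A` noise) is unobservable wherever
  the donor is absent. At the study-estimate truth with `sigma = 0.5`,
  130 sites × 3 surveys recover the negative sign in roughly 7 of 10
  replicates with pd rarely above 85%; at 1,000 sites the 90% HDI cleanly
  excludes zero (mean ≈ −2.7, pd ≈ 96%), so the estimator is consistent
  but the study-scale design is underpowered for confident sign claims —
  context for how much weight a single-study `epsilon` interval can bear.
* No missing-data support, no multi-season dynamics, no >2 species, no
  zero-inflated or negative-binomial abundance variants.
* The desk protocol trades Monte Carlo error for speed; borderline R̂
  values on weakly identified parameters are more common than under the
  full protocol.
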
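# dinmix

Two-species binomial N-mixture models with **directional interactions** on
both abundance and detection, for repeated-count surveys of interacting
species under imperfect detection.

The motivating problem comes from community ecology: two terrestrial
salamanders share forest plots and prey, and the question is whether the
dominant species suppresses the subordinate one by **exploitative
competition** (depleting resources, which should lower the subordinate's
local abundance — spatial segregation) or by **interference competition**
(behavioural exclusion, which should shift the subordinate's surface
activity in time — temporal niche partitioning). Repeated counts on a grid
of plots cannot answer this directly because detection is imperfect and
detection probability is itself the proxy for surface activity. `dinmix`
separates the two mechanisms inside one hierarchical model.

## Model

For plots `i` and surveys `j`, with species A the dominant "donor" and
species B the subordinate "receiver":

    N_iA ~ Poisson(lambda_iA)          C_ijA | N_iA ~ Binomial(N_iA, p_ijA)
    N_iB ~ Poisson(lambda_iB)          C_ijB | N_iB ~ Binomial(N_iB, p_ijB)

    logit(p_ijA) = alpha0_A + alpha_A' x_ij                    + delta_ijA
    logit(p_ijB) = alpha0_B + alpha_B' x_ij + epsilon * p_ijA  + delta_ijB
    log(lambda_iA) = beta0_A + beta_A' z_i                     + eta_iA
    log(lambda_iB) = beta0_B + beta_B' z_i  + gamma * N_iA     + eta_iB

* `gamma` — **co-abundance** term: effect of the donor's latent abundance
  on the receiver's log-abundance. Negative `gamma` = spatial segregation
  (exploitative competition).
* `epsilon` — **co-detection** term: effect of the donor's detection
  probability (a proxy for surface activity) on the receiver's
  logit-detection. Negative `epsilon` = temporal avoidance (interference
  competition).
* `eta`, `delta` — site- and observation-level normal random effects
  absorbing extra-Poisson/extra-binomial dispersion.

Both discrete latent abundances are marginalized out of the likelihood by
truncated summation, and the continuous parameters are sampled by an
adaptive Metropolis-within-Gibbs sampler (numba-compiled). Reported
summaries follow the field's conventions: posterior mean, 90% highest
density interval (HDI), probability of direction (pd), split-R̂ with the
R̂ < 1.1 convergence rule, and chi-square posterior predictive checks with
Bayesian p-values. See `docs/methods.md` for the full account.

## Worked example

The field data behind the motivating study are not public, so the package
ships a generator with exactly the model's structure, defaulting to the
study's design (26 plots × 3 surveys) and its published point estimates as
the generating truth:

```bash
dinmix simulate --out-dir demo --seed 1 --quiet
dinmix fit --counts demo/counts.csv --site-covs demo/site_covs.csv \
           --survey-covs demo/survey_covs.csv --out-dir demo/fit \
           --seed 1 --n-adapt 4000 --n-iter 12000 --n-burn 2000 --thin 10
dinmix ppc --counts demo/counts.csv --site-covs demo/site_covs.csv \
           --survey-covs demo/survey_covs.csv \
           --draws demo/fit/draws.csv --out demo/ppc.csv --seed 2
```

(`fit` first runs the Pearson collinearity screen on the covariates and
refuses to proceed when any pair has |r| ≥ 0.7 unless `--force` is given —
with only three survey occasions, simulated weather covariates trip it
often. The run above uses a mildly lengthened desk protocol; the study's
full 350,000-iteration protocol is `--protocol paper`.) The fit reports
`all R-hat < 1.1 (max 1.028)` and writes `summary.csv` with one row per
monitored quantity; selected rows:

```
    parameter   mean  hdi90_lower  hdi90_upper      pd   rhat
        gamma -0.442       -0.735       -0.153  99.967  1.008
      epsilon -4.133      -17.760        9.527  68.200  1.002
mean_lambda_A  0.283        0.073        0.481 100.000  1.009
mean_lambda_B  2.203        1.244        3.084 100.000  1.005
```

Read: the receiver is several times more abundant than the donor (2.2 vs
0.28 expected individuals per plot), the co-abundance term's 90% HDI
excludes zero on this dataset, and the co-detection term points negative
(posterior mean −4.1, near the generating −3.76) but with a pd of only
68% — at 26 plots a single dataset rarely pins `epsilon` down, which is
itself part of the scientific story (see the methods note on
identifiability). The PPC step prints `Bayesian p: species A = 0.510,
species B = 0.703`: both near the middle of (0, 1), so the model
reproduces its own data's dispersion.

The `analysis/` directory holds the same pipeline as numbered scripts
(simulate → fit → posterior checks → parameter recovery → interaction
detection), each writing its table under `results/`.

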
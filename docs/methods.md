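# Methods

## Model

Observed scores are bounded (e.g. FEV1 as % predicted in [0, 100], daily time
on ventilator in [0, 24] hours), so each observation is mapped linearly to
[0, 1] and modelled with a beta likelihood parameterized by mean and
precision:

    y_ij ~ Beta(mu_ij * nu, (1 - mu_ij) * nu)
    logit(mu_ij) = alpha_i + beta_i * (T + t_ij)

* `t_ij` — months since patient *i*'s first visit; `T` centres time.
* `(alpha_i, beta_i)` — patient-level intercept and slope on the logit scale,
  bivariate normal across patients with unstructured covariance
  (sds `sigma_a`, `sigma_b`, correlation `rho`). The family and the presence
  of a correlation are modelling choices; the data rarely identify `rho`
  sharply and the prior on it is uniform.
* `nu` — a single shared precision per fitted model ("sample size" of the
  beta: `Var[y] = mu(1-mu)/(1+nu)`). With ~5 visits per patient an
  observation-specific precision is not identifiable; per-stratum fits (by
  genotype or age class, via `LongitudinalDataset.subset`) are the supported
  way to let precision vary.

Trajectories are exactly linear in time on the logit scale, hence
approximately linear on the raw scale away from the bounds — a reasonable
assumption over trial-length horizons (6–24 months) for slowly progressing
congenital myopathies, and the reason predictions saturate gracefully near
the score bounds instead of escaping them.

**Boundary squeeze.** The beta density is undefined at 0 and 1, so scaled
values are compressed as `(y * (N - 1) + 0.5) / N` with `N` the number of
observations in the dataset. The map is linear and exactly invertible
(`unscale_score`); with `N = 295` a boundary score moves by ~0.17% of the
range. The same `N` must be used for scaling and unscaling.

**Priors** (`PriorSpec` defaults, all configurable): Normal(0, 10) on the
population intercept and slope (logit scale — essentially flat over the
plausible range); half-Normal(5) on both random-effect sds; uniform on
[-1, 1] for the correlation; Normal(0, 5) on log(nu). These are diffuse
relative to the likelihood for any realistically sized cohort.

## Sampler

`fit_mcmc` runs an adaptive Metropolis-within-Gibbs scheme written for this
model's structure:

1. Per-patient intercepts, then slopes: conditionally independent given the
   population block, so all patients are updated in parallel with vectorized
   random-walk Metropolis (per-patient scales adapted to 44% acceptance).
2. Population mean: exact conjugate bivariate-normal Gibbs update.
3. Covariance block `(log sigma_a, log sigma_b, atanh rho)`: adaptive 3-d
   random-walk Metropolis in the centred frame, followed by the same block in
   the *non-centred* frame (effects re-expressed as standardized residuals
   and moved together with the scales). This interleaving (ASIS) is what
   makes the scale parameters mix: the centred update alone stalls in the
   funnel where shrunken effects pin the sds.
4. `log nu`: 1-d adaptive random-walk Metropolis.

Adaptation (Robbins–Monro step-size tuning and an empirical proposal
covariance for the 3-d block) runs only during warmup and is frozen
afterwards, so retained draws come from valid Markov chains. Initialization
is empirical (per-patient logit-scale least squares plus chain-specific
jitter, so chains start overdispersed). Internally time is re-centred at the
mean observation time for geometry and draws are mapped back to the dataset's
parameterization afterwards.

Defaults: 2 chains, 1000 warmup + 1000 retained draws, split-Rhat limit 1.05,
minimum population-parameter ESS 400. A fit exceeding either limit is
returned in a flagged state (`converged=False`, warnings emitted), never as a
silent success; at default sizes the slowest parameters (the random-effect
sds) typically need 2000–5000 retained draws to clear ESS 400, which takes a
few seconds for a 59-patient cohort.

Determinism: all randomness flows from the `seed` argument through
`numpy.random.SeedSequence`; identical seed and configuration give
bit-identical draws.

## Time origin

`read_longitudinal_csv` defaults to `T = -mean(t)` so the intercept refers to
the cohort's mean observation time. `simulate_cohort` emits datasets with
`T = 0` because its generating intercept is defined at the first visit; the
parameter-recovery tests therefore compare like with like. The sampler's
internal re-centring makes the choice immaterial for mixing.

## Prediction

`predict_individual` pushes every posterior draw of `(alpha_i, beta_i, nu)`
through the beta/logit law at the requested future times: trajectories carry
parameter and observation-level uncertainty, and only pre-treatment data
enter (through the posterior itself). For run-in-only enrolees,
`predict_run_in` draws new-patient effects from each posterior draw's
population distribution, re-weights by the run-in beta likelihood, and
systematically resamples (importance-ESS warning below 200;
`predict_run_in_refit` is the exact slow path that refits with the run-in
patient included). With a flat run-in likelihood this reduces exactly to the
population-marginal predictive. Run-in predictions are markedly wider than
those of patients with years of follow-up — the borrowing is real but
moderate — and interval width near the score bounds shrinks automatically
through the beta variance function; no explicit correction is applied.

`joint_improvement_probability` estimates the orthant probability
`P(trajectory at least as extreme as observed at all times)` from the
predictive draws (default ≥ 4000; Monte-Carlo SE reported). Comparisons are
inclusive (`>=`/`<=`), immaterial for continuous draws.

## Null calibration of the responder rule — an important subtlety

For a **single** future visit the statistic is an exact predictive p-value:
under no treatment effect it is uniform, so `P(statistic <= c) = c` (up to
the finite-draw tie term `(floor(cN)+1)/(N+1)`). For **k** visits the joint
statistic is, conditionally on the patient's effects, a product of k
independent uniforms, and

    P(joint statistic <= c) = c * sum_{j<k} (-ln c)^j / j!

which is **0.162** for the default c = 0.01 and k = 3 — far above the
nominal cutoff. The responder rule is therefore *not* per-patient calibrated
at its cutoff for multi-visit trials; what controls the trial's error rate is
the downstream threshold calibration, which simulates the null responder
count with the correct rate `q(c, k)` (`null_responder_rate`). The fast
shortcut simulates responder indicators as Bernoulli(q); the full per-patient
pipeline (`mode="pipeline"`, or `method="exact"` for the analytic product of
beta tails) agrees with it within Monte-Carlo error, as the tests verify.

## Trial engine

Per simulated null trial of n patients, the responder count k gives a
conjugate posterior Beta(a + k, b + n - k) for the responder rate (uniform
prior by default). The null reference distribution of the rate is a beta
fitted by moments to the simulated null trial rates (a degenerate-at-q
alternative is provided). The decision statistic is the Monte-Carlo
probability `P(p_obs > p_null)` with independent draws; since it depends on a
trial only through k, it is computed once per distinct count.
`calibrate_threshold` returns the smallest threshold on a 0.01 grid whose
null rejection rate is ≤ alpha (strict-inequality rejection resolves grid
ties conservatively).

Under the default design (n = 12, cutoff 0.01, 3 visits, alpha 0.05) the
calibrated threshold is 0.89 ± one grid step across seeds and the achieved
Type I error ≈ 3.2% — the bound cannot be met exactly because the responder
count is discrete: the rule ends up rejecting at ≥ 4 responders, the finest
attainable step below 5%.

`assurance_curve` recalibrates the threshold per sample size, then sweeps the
increase Δ in responder rate: counts ~ Binomial(n, q + Δ), success fraction
recorded. The point at Δ = 0 is the Type I estimate; curves are
non-decreasing in Δ and pointwise higher for n = 24 than n = 12. These
operating characteristics depend on the endpoint only through the responder
definition, so responder statuses from different endpoints and age classes
pool into one count.

## Synthetic cohorts

`simulate_cohort` emulates the study structure the analysis assumes:
59 patients (44 *MTM1*, 15 *DNM2*), age strata {0–2: 12, 2–6: 11, 6–16: 14,
>16: 22} with baseline age uniform within stratum, follow-up uniform on
12–48 months, and the age-dependent visit schedule (3-monthly under age 2,
6-monthly at 2–6, months 6 and 12 then yearly for patients enrolled above 6).
Default generating parameters — intercept 0.2, slope −0.002/month, re sds 0.8
and 0.01, correlation 0, nu 60 — are *invented plausible values* describing a
slowly declining bounded score with large level heterogeneity; no fitted
estimates from the real cohort are published to anchor them. The generator
draws scores from the model itself, so passing tests demonstrate internal
consistency (correct inference, calibrated prediction, controlled error
rates) under the assumed data-generating process; they cannot demonstrate
robustness to model misspecification, placebo effects, drop-out, mortality,
or rare events (e.g. hospitalisation-induced decline), none of which are
simulated.

## Problem sizes and numerical choices

Calibration and assurance use 10,000 simulated trials with 200,000
Monte-Carlo draws per distinct responder count; per-patient null simulations
use 10,000 patients × 4,000 predictive draws; coverage checks use 5,000
patients; parameter recovery uses 20 replicate 59-patient cohorts fitted with
2 chains × (600 warmup + 1000 draws). Degenerate inputs are handled
explicitly: a single-patient dataset fits (prior-dominated random-effect
posteriors), an empty future-time vector yields empty trajectories, a
degenerate null-rate sample raises instead of fitting a beta, and responder
rates pushed above 1 by a large effect are clipped with a warning.

## Known limitations

* Linear logit-scale trajectories cannot represent late-life nonlinearity;
  predictions degrade with horizon, as they must.
* A stabilising treatment in a stable disease is undetectable by design —
  the responder rule detects departure from the predicted course.
* The shared-`nu` choice trades observation-level variance flexibility for
  identifiability.
* The run-in importance resampler degrades (low ESS) when run-in data are
  many or extreme relative to the population posterior; the refit path is
  exact but slow.
* Type I control is exact only under the generating model; placebo effects
  and model misspecification are out of scope here.
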
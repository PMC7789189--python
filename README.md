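# betaprog

Hierarchical Bayesian disease-progression modelling of bounded clinical
scores, and single-arm responder-trial design built on it.

## Who this is for

Designing an adequately powered placebo-controlled trial is often impossible
in very rare diseases such as centronuclear myopathy (CNM): cohorts are tiny
and clinically heterogeneous. An alternative is to let **each patient act as
their own control**: model the natural history of the disease from
observational follow-up, predict each enrolee's *untreated* evolution, and
declare a response when the observed post-treatment trajectory would have been
very unlikely without intervention. `betaprog` implements that strategy end to
end for bounded endpoints — FEV1 (% predicted), FVC, time on ventilator,
CHOP-INTEND, MFM scales — including the trial operating characteristics
(Type I error calibration and assurance curves).

## The model

A bounded score is rescaled to the open unit interval and given a beta
likelihood whose mean follows a patient-specific trajectory, linear on the
logit scale:

```
y_ij ~ Beta(a_ij, b_ij),   a_ij = mu_ij * nu,  b_ij = (1 - mu_ij) * nu
logit(mu_ij) = alpha_i + beta_i * (T + t_ij)
```

with `i` indexing patients, `t_ij` months since the patient's first visit, and
`T` a time-centering constant. The precision `nu` (the beta "sample size",
`Var[y] = mu(1-mu)/(1+nu)`) is shared within a fit; the random intercepts and
slopes `(alpha_i, beta_i)` are bivariate normal across patients. Fitting is by
MCMC (adaptive Metropolis-within-Gibbs with conjugate population-mean updates
and an interleaved non-centred covariance step), with split-Rhat and ESS
diagnostics via ArviZ.

On top of the fitted model:

* **Individual prediction** — per-patient predictive distributions of
  untreated evolution at future visits (parameter *and* observation-level
  uncertainty); importance-resampling "borrowing" for enrolees with only a
  short pre-treatment run-in.
* **Responder rule** — a patient is a responder when the joint predictive
  probability of their observed improvement at all post-treatment visits
  (an orthant probability) is ≤ 0.01.
* **Trial engine** — simulated null trials calibrate the decision threshold
  `c` so that declaring success when
  `P(rate_observed > rate_null | data) > c` keeps the overall Type I error
  ≤ 5%, and assurance (expected power) curves are computed against the
  increase in responder rate.

Because the real natural-history cohort is not publicly deposited, the
package ships a first-class synthetic-cohort generator with the study's
structure (59 patients: 44 *MTM1*, 15 *DNM2*; four age strata; age-dependent
visit schedules; 1–4 years of follow-up).

## Worked example

```python
import numpy as np
import betaprog as bp
from betaprog import predictive as pv, trial_engine as te

cohort = bp.simulate_cohort(bp.CohortConfig(seed=1))      # 59 patients, 310 visits
draws = bp.fit_mcmc(cohort, n_chains=2, n_iter=2000, n_warmup=1000, seed=1)
print(draws.summary().round(4))
```

```
                    mean      sd    rhat        ess
pop_intercept     0.2557  0.1189  1.0001  3035.1974
pop_slope        -0.0014  0.0021  1.0034   406.5001
re_sd_intercept   0.8998  0.0943  1.0159   141.0655
re_sd_slope       0.0105  0.0024  1.0103   134.1691
re_correlation    0.1346  0.2523  1.0117   139.1795
precision_nu     58.8710  5.5332  1.0011   438.8833
```

The posterior recovers the generating population (intercept 0.2, slope
−0.002/month, sds 0.8 and 0.01, nu 60) within its uncertainty, and the fit
check reports 99.4% of observations inside their 95% posterior-predictive
intervals. Predicting one patient 2, 4 and 6 months past their last visit and
testing observed values sitting at each visit's 97th percentile:

```python
pid = cohort.patient_ids[0]
last = max(o.time_months for o in cohort.patient_observations(pid))
pred = pv.predict_individual(draws, pid, last + np.array([2., 4., 6.]), seed=1)
jp = pv.joint_improvement_probability(pred, observed, "increase")
# joint improvement probability: 0.0013 (MC SE 0.0006)
```

Each value alone is inside its 95% interval, yet the *joint* probability of
all three is 0.0013 ≤ 0.01, so this patient is called a responder — the
statistic rewards consistent improvement across visits. Calibrating the
default 12-patient design:

```python
cal = te.calibrate_design(bp.TrialDesign(), n_trials=10_000, seed=1)
t1 = te.estimate_type1(cal, n_trials=10_000, seed=2)
# calibrated threshold: 0.89; fresh Type I estimate: 0.031
```

A decision threshold of 0.89 keeps the overall false-positive rate of the
trial at ~3%, below the 5% bound. `te.assurance_curve` then yields expected
power as a function of the treatment-induced increase in responder rate, for
n = 12 and n = 24.

A `betaprog` command-line tool wraps the same pipeline
(`simulate`, `fit`, `predict`, `call`, `calibrate`, `assure`, `run-all`) with
YAML configuration; see `betaprog --help`.

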
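"""Synthetic natural-history cohorts for centronuclear myopathy.

The real NatHis-CNM data are not publicly deposited, so this module generates
cohorts with the statistical structure the analysis assumes: 59 patients by
default (44 *MTM1*, 15 *DNM2*) spread over four age strata, an age-dependent
visit schedule (every 3 months under age 2, every 6 months between 2 and 6,
visits at months 6 and 12 then yearly above 6), heterogeneous follow-up, and
bounded scores drawn from the hierarchical beta/logit model itself.

The default generating parameters are synthetic: plausible values chosen to
mimic a slowly, near-linearly evolving bounded score with large between-patient
heterogeneity in level and small heterogeneity in slope.  They are not
estimates from any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .core_model import (
    ENDPOINTS,
    EndpointSpec,
    LongitudinalDataset,
    ModelParameters,
    Observation,
    PatientMeta,
    unscale_score,
)

__all__ = [
    "AGE_STRATA",
    "DEFAULT_STRATUM_COUNTS",
    "default_generating_parameters",
    "CohortConfig",
    "TreatmentEffectSpec",
    "visit_schedule",
    "simulate_cohort",
    "simulate_future",
]

#: Age strata (years) used for cohort composition: label -> (low, high).
AGE_STRATA: dict[str, tuple[float, float]] = {
    "0-2": (0.0, 2.0),
    "2-6": (2.0, 6.0),
    "6-16": (6.0, 16.0),
    ">16": (16.0, 50.0),
}

#: Default number of patients per age stratum (totals 59).
DEFAULT_STRATUM_COUNTS: dict[str, int] = {"0-2": 12, "2-6": 11, "6-16": 14, ">16": 22}


def default_generating_parameters() -> ModelParameters:
    """Synthetic population defaults (logit scale, months).

    Intercept 0.2 (score slightly above mid-range at entry), slope -0.002 per
    month (slow decline), between-patient sds 0.8 (level) and 0.01 (slope),
    uncorrelated, precision nu = 60.
    """
    return ModelParameters(
        pop_intercept_mean=0.2,
        pop_slope_mean=-0.002,
        re_sd_intercept=0.8,
        re_sd_slope=0.01,
        re_correlation=0.0,
        precision_nu=60.0,
        patient_effects={},
    )


@dataclass(frozen=True)
class TreatmentEffectSpec:
    """Perturbation of a patient's trajectory from the intervention onward.

    A step on the logit scale (``intercept_shift``) plus a slope change
    (``slope_shift``, per month) applied from ``onset_time`` (months).  The
    null hypothesis of no treatment effect is the zero spec.
    """

    intercept_shift: float = 0.0
    slope_shift: float = 0.0
    onset_time: float = 0.0

    def __post_init__(self) -> None:
        if self.onset_time < 0:
            raise ValueError("onset_time must be >= 0")


NULL_EFFECT = TreatmentEffectSpec(0.0, 0.0, 0.0)


@dataclass
class CohortConfig:
    """Configuration of one synthetic natural-history cohort."""

    n_mtm1: int = 44
    n_dnm2: int = 15
    age_stratum_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_STRATUM_COUNTS)
    )
    follow_up_months: tuple[float, float] = (12.0, 48.0)
    generating_params: ModelParameters = field(default_factory=default_generating_parameters)
    endpoint: EndpointSpec = field(default_factory=lambda: ENDPOINTS["fev1_pct"])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mtm1 < 0 or self.n_dnm2 < 0:
            raise ValueError("patient counts must be >= 0")
        unknown = set(self.age_stratum_counts) - set(AGE_STRATA)
        if unknown:
            raise ValueError(f"unknown age strata: {sorted(unknown)}")
        if any(v < 0 for v in self.age_stratum_counts.values()):
            raise ValueError("stratum counts must be >= 0")
        total = self.n_mtm1 + self.n_dnm2
        if sum(self.age_stratum_counts.values()) != total:
            raise ValueError(
                f"age stratum counts sum to {sum(self.age_stratum_counts.values())}, "
                f"expected n_mtm1 + n_dnm2 = {total}"
            )
        lo, hi = self.follow_up_months
        if lo < 0 or hi < lo:
            raise ValueError("follow_up_months must satisfy 0 <= low <= high")


def visit_schedule(baseline_age_years: float, follow_up_months: float) -> np.ndarray:
    """Visit times (months since enrolment) under the age-dependent schedule.

    3-month spacing while the patient is under 2 years old, 6-month spacing
    between 2 and 6; patients enrolled above age 6 are seen at months 6 and 12
    and then once a year.  Patients ageing past a boundary switch spacing at
    the first visit on or after the boundary.
    """
    if baseline_age_years < 0:
        raise ValueError("baseline age must be >= 0")
    if follow_up_months < 0:
        raise ValueError("follow-up must be >= 0 months")
    times = [0.0]
    t = 0.0
    while True:
        age = baseline_age_years + t / 12.0
        if baseline_age_years >= 6.0:
            # months 6 and 12 after enrolment, then yearly
            dt = 6.0 if t < 12.0 else 12.0
        elif age < 2.0:
            dt = 3.0
        elif age < 6.0:
            dt = 6.0
        else:
            dt = 12.0
        t += dt
        if t > follow_up_months + 1e-9:
            break
        times.append(t)
    return np.asarray(times)


def _mu_with_effect(alpha, beta, T, times, effect: TreatmentEffectSpec):
    """Logit-linear mean with a piecewise treatment perturbation from onset."""
    times = np.asarray(times, dtype=float)
    chi = alpha + beta * (T + times)
    on = times >= effect.onset_time
    chi = chi + on * (effect.intercept_shift + effect.slope_shift * (times - effect.onset_time))
    return expit(chi)


def simulate_cohort(config: CohortConfig) -> LongitudinalDataset:
    """Draw one cohort from the generating model.

    Per patient: baseline age uniform within its stratum, follow-up uniform in
    the configured range, visits from :func:`visit_schedule`, random effects
    from the population distribution, and observations from the beta
    likelihood.  Identical seed, identical cohort.  The returned dataset uses
    centering constant T = 0, so the generating intercept is the logit-scale
    level at the first visit.
    """
    p = config.generating_params
    rng = np.random.default_rng(config.seed)
    genotypes = ["MTM1"] * config.n_mtm1 + ["DNM2"] * config.n_dnm2
    strata: list[str] = []
    for label in AGE_STRATA:  # canonical stratum order
        strata.extend([label] * config.age_stratum_counts.get(label, 0))
    if len(strata) != len(genotypes):
        raise ValueError("stratum allocation does not match patient count")

    cov = p.population_cov
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
    observations: list[Observation] = []
    patients: dict[str, PatientMeta] = {}
    for i, (geno, stratum) in enumerate(zip(genotypes, strata)):
        pid = f"P{i + 1:03d}"
        lo, hi = AGE_STRATA[stratum]
        age0 = float(rng.uniform(lo, hi))
        fup = float(rng.uniform(*config.follow_up_months))
        times = visit_schedule(age0, fup)
        eff = p.population_mean + L @ rng.standard_normal(2)
        mu = _mu_with_effect(eff[0], eff[1], 0.0, times, NULL_EFFECT)
        yv = rng.beta(mu * p.precision_nu, (1.0 - mu) * p.precision_nu)
        sex = "M" if rng.random() < 0.5 else "F"
        patients[pid] = PatientMeta(pid, geno, sex, age0)
        for t, y in zip(times, yv):
            observations.append(
                Observation(
                    patient_id=pid,
                    time_months=float(t),
                    age_years=age0 + float(t) / 12.0,
                    raw_value=config.endpoint.lower_bound + float(y) * config.endpoint.span,
                    scaled_value=float(y),
                )
            )
    return LongitudinalDataset(
        endpoint=config.endpoint,
        observations=observations,
        patients=patients,
        centering_constant=0.0,
    )


def simulate_future(
    patient_effects: tuple[float, float],
    times,
    params: ModelParameters,
    effect: TreatmentEffectSpec = NULL_EFFECT,
    seed: int = 0,
    centering_constant: float = 0.0,
) -> np.ndarray:
    """One future trajectory (scaled values) at the given times.

    Drawn from the same beta/logit law as the natural history, with the
    treatment perturbation applied from ``effect.onset_time`` onward.  The
    zero-effect spec reproduces the null generator exactly (same seed, same
    output).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    alpha, beta = patient_effects
    mu = _mu_with_effect(alpha, beta, centering_constant, times, effect)
    return rng.beta(mu * params.precision_nu, (1.0 - mu) * params.precision_nu)
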
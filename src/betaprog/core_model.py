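"""Hierarchical beta-regression disease-progression model for bounded clinical scores.

Bounded endpoints such as FEV1 (% predicted) or daily time on ventilator are
rescaled to the open unit interval and modelled with a beta likelihood whose
mean follows a patient-specific trajectory that is linear on the logit scale:

    y_ij ~ Beta(mu_ij * nu, (1 - mu_ij) * nu)
    logit(mu_ij) = chi_ij = alpha_i + beta_i * (T + t_ij)

where ``i`` indexes patients, ``j`` visits, ``t_ij`` is time in months since the
patient's first visit and ``T`` is a constant used to centre time.  The beta
parameterization is in terms of the mean ``mu`` and the precision ("sample
size") ``nu``: ``a = mu * nu``, ``b = (1 - mu) * nu``, so that
``E[y] = mu`` and ``Var[y] = mu (1 - mu) / (1 + nu)``.

Patient-level intercepts and slopes ``(alpha_i, beta_i)`` are exchangeable
draws from a bivariate normal population distribution with unstructured
covariance; one precision ``nu`` is shared by all observations of a fitted
model.  Posterior inference is by MCMC (see :mod:`betaprog._mcmc`) with
split-Rhat and effective-sample-size diagnostics.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, logit

__all__ = [
    "EndpointSpec",
    "Observation",
    "PatientMeta",
    "LongitudinalDataset",
    "ModelParameters",
    "PriorSpec",
    "PosteriorDraws",
    "FitCheck",
    "ENDPOINTS",
    "scale_score",
    "unscale_score",
    "logit_mean",
    "beta_shape",
    "beta_logpdf",
    "log_likelihood",
    "fit_mcmc",
    "posterior_fit_check",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EndpointSpec:
    """A bounded clinical score.

    Parameters
    ----------
    name
        Endpoint label, e.g. ``"fev1_pct"``.
    lower_bound, upper_bound
        Attainable score range, in raw score units.
    improvement_direction
        ``"increase"`` if higher scores are better (FEV1), ``"decrease"``
        if lower scores are better (time on ventilator).
    relevance_margin
        Minimal clinically relevant change, in raw score units (e.g. 8
        percentage points for FEV1).
    """

    name: str
    lower_bound: float
    upper_bound: float
    improvement_direction: str = "increase"
    relevance_margin: float = 0.0

    def __post_init__(self) -> None:
        if not self.lower_bound < self.upper_bound:
            raise ValueError(
                f"endpoint {self.name!r}: lower_bound must be < upper_bound "
                f"(got [{self.lower_bound}, {self.upper_bound}])"
            )
        if self.improvement_direction not in ("increase", "decrease"):
            raise ValueError(
                "improvement_direction must be 'increase' or 'decrease', got "
                f"{self.improvement_direction!r}"
            )
        if self.relevance_margin < 0:
            raise ValueError("relevance_margin must be >= 0")

    @property
    def span(self) -> float:
        return self.upper_bound - self.lower_bound


#: Built-in endpoint registry.  CHOP-INTEND has 16 items scored 0-4 (max 64);
#: the MFM scales are expressed as percentages of their maximal score; time on
#: ventilator is hours per day and improves downward.
ENDPOINTS: Mapping[str, EndpointSpec] = {
    "fev1_pct": EndpointSpec("fev1_pct", 0.0, 100.0, "increase", 8.0),
    "fvc_pct": EndpointSpec("fvc_pct", 0.0, 100.0, "increase", 0.0),
    "chop_intend": EndpointSpec("chop_intend", 0.0, 64.0, "increase", 0.0),
    "mfm20_pct": EndpointSpec("mfm20_pct", 0.0, 100.0, "increase", 0.0),
    "mfm32_pct": EndpointSpec("mfm32_pct", 0.0, 100.0, "increase", 0.0),
    "ventilator_hours": EndpointSpec("ventilator_hours", 0.0, 24.0, "decrease", 0.0),
}


@dataclass(frozen=True)
class Observation:
    """One visit-level measurement of one patient."""

    patient_id: str
    time_months: float
    age_years: float
    raw_value: float
    scaled_value: float

    def __post_init__(self) -> None:
        if not 0.0 < self.scaled_value < 1.0:
            raise ValueError(
                f"patient {self.patient_id!r} at t={self.time_months}: scaled "
                f"value {self.scaled_value} is not strictly inside (0, 1)"
            )
        if self.time_months < 0:
            raise ValueError(
                f"patient {self.patient_id!r}: negative visit time {self.time_months}"
            )


@dataclass(frozen=True)
class PatientMeta:
    patient_id: str
    genotype: str = "MTM1"
    sex: str = "M"
    baseline_age_years: float = 0.0


@dataclass
class LongitudinalDataset:
    """Per-patient, per-visit scaled observations of one endpoint.

    ``centering_constant`` is the time-centering constant ``T`` (months) used
    by the logit-linear predictor ``alpha_i + beta_i * (T + t)``.
    """

    endpoint: EndpointSpec
    observations: list[Observation]
    patients: dict[str, PatientMeta]
    centering_constant: float = 0.0

    def __post_init__(self) -> None:
        if not self.observations:
            raise ValueError("dataset has no observations")
        if not np.isfinite(self.centering_constant):
            raise ValueError("centering_constant must be finite")
        seen = {o.patient_id for o in self.observations}
        missing = seen - set(self.patients)
        if missing:
            raise ValueError(f"observations reference unknown patients: {sorted(missing)}")
        empty = set(self.patients) - seen
        if empty:
            raise ValueError(f"patients without observations: {sorted(empty)}")

    # -- array views used by the sampler and the predictive machinery -------

    @property
    def patient_ids(self) -> list[str]:
        return list(self.patients)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def __len__(self) -> int:
        return len(self.observations)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(y, t, patient_index)`` aligned arrays, patients in
        ``patient_ids`` order."""
        order = {pid: k for k, pid in enumerate(self.patient_ids)}
        y = np.array([o.scaled_value for o in self.observations])
        t = np.array([o.time_months for o in self.observations])
        idx = np.array([order[o.patient_id] for o in self.observations])
        return y, t, idx

    def patient_observations(self, patient_id: str) -> list[Observation]:
        return [o for o in self.observations if o.patient_id == patient_id]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for o in self.observations:
            meta = self.patients[o.patient_id]
            rows.append(
                {
                    "patient_id": o.patient_id,
                    "genotype": meta.genotype,
                    "sex": meta.sex,
                    "age_years": o.age_years,
                    "time_months": o.time_months,
                    "endpoint": self.endpoint.name,
                    "value": o.raw_value,
                }
            )
        return pd.DataFrame(rows)

    def subset(self, patient_ids: Iterable[str]) -> "LongitudinalDataset":
        """Independent-fit stratification support: restrict to a patient set."""
        keep = set(patient_ids)
        obs = [o for o in self.observations if o.patient_id in keep]
        pats = {p: m for p, m in self.patients.items() if p in keep}
        return LongitudinalDataset(self.endpoint, obs, pats, self.centering_constant)


@dataclass
class ModelParameters:
    """One full set of model parameters (population block + patient effects)."""

    pop_intercept_mean: float
    pop_slope_mean: float
    re_sd_intercept: float
    re_sd_slope: float
    re_correlation: float
    precision_nu: float
    patient_effects: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.precision_nu <= 0:
            raise ValueError(f"precision_nu must be > 0, got {self.precision_nu}")
        if self.re_sd_intercept <= 0 or self.re_sd_slope <= 0:
            raise ValueError("random-effect standard deviations must be > 0")
        if abs(self.re_correlation) > 1:
            raise ValueError(f"|re_correlation| must be <= 1, got {self.re_correlation}")

    @property
    def population_mean(self) -> np.ndarray:
        return np.array([self.pop_intercept_mean, self.pop_slope_mean])

    @property
    def population_cov(self) -> np.ndarray:
        sa, sb, r = self.re_sd_intercept, self.re_sd_slope, self.re_correlation
        return np.array([[sa * sa, r * sa * sb], [r * sa * sb, sb * sb]])


@dataclass(frozen=True)
class PriorSpec:
    """Diffuse priors, made concrete.

    Wide zero-centred normals on the population intercept and slope (logit
    scale), half-normal scales on the random-effect standard deviations,
    a correlation uniform on [-1, 1], and a wide normal on log(nu).
    """

    intercept_loc: float = 0.0
    intercept_scale: float = 10.0
    slope_loc: float = 0.0
    slope_scale: float = 10.0
    re_sd_scale: float = 5.0
    log_nu_loc: float = 0.0
    log_nu_scale: float = 5.0

    def __post_init__(self) -> None:
        for name in ("intercept_scale", "slope_scale", "re_sd_scale", "log_nu_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class PosteriorDraws:
    """MCMC draws of all model parameters, indexed by (chain, iteration).

    Population-level arrays have shape ``(n_chains, n_draws)``; the
    patient-effect arrays ``alpha`` and ``beta`` have shape
    ``(n_chains, n_draws, n_patients)`` aligned with ``patient_ids``.
    """

    pop_intercept: np.ndarray
    pop_slope: np.ndarray
    re_sd_intercept: np.ndarray
    re_sd_slope: np.ndarray
    re_correlation: np.ndarray
    precision_nu: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    patient_ids: list[str]
    centering_constant: float
    endpoint: EndpointSpec
    seed: int
    priors: PriorSpec
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)
    converged: bool = True
    warnings_: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pop_intercept.ndim != 2 or self.pop_intercept.shape[0] < 2:
            raise ValueError("draws must have >= 2 chains of equal length")
        if self.alpha.shape != (*self.pop_intercept.shape, len(self.patient_ids)):
            raise ValueError("alpha draws misaligned with patient_ids")
        if np.any(self.precision_nu <= 0) or np.any(self.re_sd_intercept <= 0):
            raise ValueError("invalid draws: nu and random-effect sds must be > 0")

    @property
    def n_chains(self) -> int:
        return self.pop_intercept.shape[0]

    @property
    def n_draws(self) -> int:
        return self.pop_intercept.shape[1]

    def patient_index(self, patient_id: str) -> int:
        try:
            return self.patient_ids.index(patient_id)
        except ValueError:
            raise KeyError(f"unknown patient {patient_id!r}") from None

    def flat(self, name: str) -> np.ndarray:
        """Flatten a variable across chains: shape (chain*draw, ...)."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def parameters_at(self, chain: int, draw: int) -> ModelParameters:
        return ModelParameters(
            pop_intercept_mean=float(self.pop_intercept[chain, draw]),
            pop_slope_mean=float(self.pop_slope[chain, draw]),
            re_sd_intercept=float(self.re_sd_intercept[chain, draw]),
            re_sd_slope=float(self.re_sd_slope[chain, draw]),
            re_correlation=float(self.re_correlation[chain, draw]),
            precision_nu=float(self.precision_nu[chain, draw]),
            patient_effects={
                pid: (float(self.alpha[chain, draw, k]), float(self.beta[chain, draw, k]))
                for k, pid in enumerate(self.patient_ids)
            },
        )

    def summary(self) -> pd.DataFrame:
        """Posterior mean/sd for the population block, joined with diagnostics."""
        rows = {}
        for name in (
            "pop_intercept",
            "pop_slope",
            "re_sd_intercept",
            "re_sd_slope",
            "re_correlation",
            "precision_nu",
        ):
            x = self.flat(name)
            rows[name] = {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1))}
        out = pd.DataFrame(rows).T
        if not self.diagnostics.empty:
            out = out.join(self.diagnostics, how="left")
        return out

    @classmethod
    def from_parameters(
        cls,
        params: ModelParameters,
        endpoint: EndpointSpec,
        centering_constant: float = 0.0,
        n_chains: int = 2,
        n_draws: int = 1000,
        seed: int = 0,
    ) -> "PosteriorDraws":
        """Degenerate (point-mass) draws replicating fixed parameters.

        Useful for analytic checks: the posterior predictive of a point-mass
        posterior is the generating distribution itself.
        """
        pids = list(params.patient_effects)
        shape = (n_chains, n_draws)
        ones = np.ones(shape)
        eff = np.array([params.patient_effects[p] for p in pids]) if pids else np.zeros((0, 2))
        return cls(
            pop_intercept=params.pop_intercept_mean * ones,
            pop_slope=params.pop_slope_mean * ones,
            re_sd_intercept=params.re_sd_intercept * ones,
            re_sd_slope=params.re_sd_slope * ones,
            re_correlation=params.re_correlation * ones,
            precision_nu=params.precision_nu * ones,
            alpha=np.broadcast_to(eff[:, 0], (*shape, len(pids))).copy(),
            beta=np.broadcast_to(eff[:, 1], (*shape, len(pids))).copy(),
            patient_ids=pids,
            centering_constant=centering_constant,
            endpoint=endpoint,
            seed=seed,
            priors=PriorSpec(),
        )

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Persist to an .npz archive with an embedded JSON header."""
        header = {
            "patient_ids": self.patient_ids,
            "centering_constant": self.centering_constant,
            "endpoint": self.endpoint.__dict__,
            "seed": self.seed,
            "priors": self.priors.__dict__,
            "converged": self.converged,
            "warnings": self.warnings_,
            "diagnostics": self.diagnostics.to_json(),
        }
        np.savez_compressed(
            path,
            header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
            pop_intercept=self.pop_intercept,
            pop_slope=self.pop_slope,
            re_sd_intercept=self.re_sd_intercept,
            re_sd_slope=self.re_sd_slope,
            re_correlation=self.re_correlation,
            precision_nu=self.precision_nu,
            alpha=self.alpha,
            beta=self.beta,
        )

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        with np.load(path) as z:
            header = json.loads(bytes(z["header"]).decode())
            diag = pd.read_json(io.StringIO(header["diagnostics"]))
            return cls(
                pop_intercept=z["pop_intercept"],
                pop_slope=z["pop_slope"],
                re_sd_intercept=z["re_sd_intercept"],
                re_sd_slope=z["re_sd_slope"],
                re_correlation=z["re_correlation"],
                precision_nu=z["precision_nu"],
                alpha=z["alpha"],
                beta=z["beta"],
                patient_ids=list(header["patient_ids"]),
                centering_constant=header["centering_constant"],
                endpoint=EndpointSpec(**header["endpoint"]),
                seed=header["seed"],
                priors=PriorSpec(**header["priors"]),
                diagnostics=diag,
                converged=header["converged"],
                warnings_=list(header["warnings"]),
            )


# ---------------------------------------------------------------------------
# Link / likelihood math
# ---------------------------------------------------------------------------


def scale_score(raw, endpoint: EndpointSpec, n_obs: int, context: str = ""):
    """Map a raw score to the open unit interval.

    First a linear map to [0, 1], then the boundary squeeze
    ``(y * (N - 1) + 0.5) / N`` with ``N = n_obs`` so that values exactly at
    the bounds land strictly inside (0, 1) where the beta density is defined.
    The squeeze is exactly invertible (:func:`unscale_score`).
    """
    raw = np.asarray(raw, dtype=float)
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    bad = (raw < endpoint.lower_bound) | (raw > endpoint.upper_bound)
    if np.any(bad):
        where = f" ({context})" if context else ""
        raise ValueError(
            f"value {np.atleast_1d(raw)[np.atleast_1d(bad)][0]} outside bounds "
            f"[{endpoint.lower_bound}, {endpoint.upper_bound}] of endpoint "
            f"{endpoint.name!r}{where}"
        )
    u = (raw - endpoint.lower_bound) / endpoint.span
    out = (u * (n_obs - 1) + 0.5) / n_obs
    return float(out) if out.ndim == 0 else out


def unscale_score(scaled, endpoint: EndpointSpec, n_obs: int):
    """Inverse of :func:`scale_score` (exact up to floating point)."""
    scaled = np.asarray(scaled, dtype=float)
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    u = (scaled * n_obs - 0.5) / (n_obs - 1) if n_obs > 1 else np.full_like(scaled, 0.5)
    out = endpoint.lower_bound + u * endpoint.span
    return float(out) if out.ndim == 0 else out


def logit_mean(alpha, beta, T, t):
    """Mean of the beta likelihood: ``mu = expit(alpha + beta * (T + t))``.

    Saturates smoothly in (0, 1); strictly increasing in ``alpha`` and
    increasing in ``t`` iff ``beta > 0``.
    """
    alpha, beta, t = np.asarray(alpha, float), np.asarray(beta, float), np.asarray(t, float)
    out = expit(alpha + beta * (T + t))
    return float(out) if out.ndim == 0 else out


def beta_shape(mu, nu):
    """Beta shapes from mean/precision: ``(a, b) = (mu * nu, (1 - mu) * nu)``."""
    mu, nu = np.asarray(mu, float), np.asarray(nu, float)
    if np.any(mu <= 0) or np.any(mu >= 1):
        raise ValueError("mu must lie strictly inside (0, 1); squeeze scores first")
    if np.any(nu <= 0):
        raise ValueError("nu must be > 0")
    a, b = mu * nu, (1.0 - mu) * nu
    if a.ndim == 0:
        return float(a), float(b)
    return a, b


def beta_logpdf(y, a, b):
    """Beta log-density, written out explicitly via betaln."""
    y, a, b = np.asarray(y, float), np.asarray(a, float), np.asarray(b, float)
    return (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y) - betaln(a, b)


def log_likelihood(dataset: LongitudinalDataset, params: ModelParameters) -> float:
    """Total beta log-likelihood of a dataset under one parameter set."""
    y, t, idx = dataset.arrays()
    pids = dataset.patient_ids
    missing = [p for p in pids if p not in params.patient_effects]
    if missing:
        raise KeyError(f"patient_effects missing entries for {missing}")
    eff = np.array([params.patient_effects[p] for p in pids])
    mu = logit_mean(eff[idx, 0], eff[idx, 1], dataset.centering_constant, t)
    a, b = beta_shape(mu, params.precision_nu)
    return float(np.sum(beta_logpdf(y, a, b)))


# ---------------------------------------------------------------------------
# Fitting and fit checks
# ---------------------------------------------------------------------------


def fit_mcmc(
    dataset: LongitudinalDataset,
    priors: PriorSpec | None = None,
    n_chains: int = 2,
    n_iter: int = 1000,
    n_warmup: int = 1000,
    seed: int = 0,
    rhat_limit: float = 1.05,
    min_ess: float = 400.0,
) -> PosteriorDraws:
    """Fit the hierarchical beta/logit model by MCMC.

    An adaptive Metropolis-within-Gibbs sampler tailored to the model's
    structure: the per-patient random effects are conditionally independent
    given the population block and are updated in parallel; the population
    mean is a conjugate normal update; the random-effect covariance and the
    precision ``nu`` use adaptive random-walk blocks.  Adaptation runs only
    during warmup, so the retained chains are valid Markov chains.

    Identical ``seed`` and configuration yield bit-identical draws.  If any
    split-Rhat exceeds ``rhat_limit`` or any population-parameter ESS falls
    below ``min_ess``, the result is flagged (``converged=False`` plus a
    warning), never silently returned as a success.
    """
    from . import _mcmc

    if priors is None:
        priors = PriorSpec()
    if n_chains < 2:
        raise ValueError("n_chains must be >= 2 for split-Rhat diagnostics")
    return _mcmc.run_sampler(
        dataset,
        priors,
        n_chains=n_chains,
        n_warmup=n_warmup,
        n_draws=n_iter,
        seed=seed,
        rhat_limit=rhat_limit,
        min_ess=min_ess,
    )


@dataclass
class FitCheck:
    """Posterior-predictive adequacy summary for a fitted dataset."""

    fitted: pd.DataFrame  # per observation: posterior-mean mu, interval, inside
    coverage: float
    level: float


def posterior_fit_check(
    draws: PosteriorDraws,
    dataset: LongitudinalDataset,
    level: float = 0.95,
    seed: int = 0,
) -> FitCheck:
    """Fitted trajectories and predictive-interval coverage, per observation.

    For every observation the posterior mean of ``mu_ij`` and a central
    ``level`` posterior-predictive interval (parameter and observation-level
    uncertainty) are computed; the reported coverage is the fraction of
    observed values inside their interval.
    """
    if draws.endpoint != dataset.endpoint:
        raise ValueError(
            f"endpoint mismatch: draws are for {draws.endpoint.name!r}, "
            f"dataset is {dataset.endpoint.name!r}"
        )
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    y, t, idx = dataset.arrays()
    order = [draws.patient_index(p) for p in dataset.patient_ids]
    al = draws.flat("alpha")[:, order]  # (S, n_pat)
    be = draws.flat("beta")[:, order]
    nu = draws.flat("precision_nu")[:, None]
    rng = np.random.default_rng(seed)
    chi = al[:, idx] + be[:, idx] * (draws.centering_constant + t)[None, :]
    mu = expit(chi)  # (S, n_obs)
    ysim = rng.beta(mu * nu, (1.0 - mu) * nu)
    lo, hi = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
    qlo = np.quantile(ysim, lo, axis=0)
    qhi = np.quantile(ysim, hi, axis=0)
    inside = (y >= qlo) & (y <= qhi)
    fitted = pd.DataFrame(
        {
            "patient_id": [o.patient_id for o in dataset.observations],
            "time_months": t,
            "observed": y,
            "mu_mean": mu.mean(axis=0),
            "pi_lower": qlo,
            "pi_upper": qhi,
            "inside": inside,
        }
    )
    return FitCheck(fitted=fitted, coverage=float(inside.mean()), level=level)
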
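"""Single-arm trial design from individual predictive distributions.

Each trial patient acts as their own control: a patient is a responder when
the joint predictive probability of their observed post-treatment improvement
under the untreated predictive is at most the responder cutoff (default 0.01).
The trial's key endpoint is the responder rate.  Trial success is declared
when the posterior probability that the observed responder rate exceeds the
null (natural visit-to-visit variability) rate passes a decision threshold,
which is calibrated by simulating null trials so that the overall Type I error
stays at or below a bound (default 5%).

Null responder rate.  For ``k`` post-treatment visits, the joint orthant
statistic under the null is distributed (given a patient's effects) as a
product of ``k`` independent uniforms, so the per-patient null responder
probability at cutoff ``c`` is

    q(c, k) = c * sum_{j=0}^{k-1} (-ln c)^j / j!

For the default cutoff 0.01 over 3 visits, q = 0.162; only for a single visit
does q equal the cutoff.  The fast analytic shortcut simulates responder
indicators as Bernoulli(q); the full pipeline (simulating patients, futures
and Monte-Carlo joint probabilities) agrees with it and is available as a
cross-check and for posterior-based generators.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .core_model import EndpointSpec, ModelParameters

__all__ = [
    "ResponderCall",
    "TrialDesign",
    "TrialOperatingCharacteristics",
    "NullCalibration",
    "CalibrationError",
    "call_responder",
    "null_responder_rate",
    "null_joint_probabilities",
    "simulate_null_counts",
    "simulate_null_trial",
    "posterior_responder_rate",
    "fit_null_rate_distribution",
    "prob_rate_difference_positive",
    "null_trial_probabilities",
    "calibrate_threshold",
    "calibrate_design",
    "estimate_type1",
    "assurance_curve",
]


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ResponderCall:
    patient_id: str
    joint_probability: float
    is_responder: bool
    clinically_relevant: bool
    observed_change: float


@dataclass(frozen=True)
class TrialDesign:
    """Design constants of the single-arm responder trial."""

    n_patients: int = 12
    n_future_visits: int = 3
    responder_cutoff: float = 0.01
    decision_threshold: float | None = None  # set by calibration
    alpha: float = 0.05
    rate_prior: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if not 0 < self.responder_cutoff < 1:
            raise ValueError("responder_cutoff must be in (0, 1)")
        if self.decision_threshold is not None and not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_patients < 1 or self.n_future_visits < 1:
            raise ValueError("n_patients and n_future_visits must be >= 1")
        if min(self.rate_prior) <= 0:
            raise ValueError("rate_prior shapes must be > 0")


@dataclass
class TrialOperatingCharacteristics:
    type1_error: float
    calibrated_threshold: float
    assurance: pd.DataFrame  # columns: delta, n, power
    n_sim: int
    seed: int

    def __post_init__(self) -> None:
        if not 0 <= self.type1_error <= 1:
            raise ValueError("type1_error must be in [0, 1]")


# ---------------------------------------------------------------------------
# Responder calling
# ---------------------------------------------------------------------------


def call_responder(
    joint_probability: float,
    observed_change: float,
    design: TrialDesign,
    endpoint: EndpointSpec,
    patient_id: str = "",
) -> ResponderCall:
    """Apply the responder rule (inclusive cutoff) and, separately, the
    clinical-relevance margin in the endpoint's improvement direction."""
    jp = float(joint_probability)
    if not 0 <= jp <= 1:
        raise ValueError("joint_probability must be in [0, 1]")
    if endpoint.improvement_direction == "increase":
        relevant = observed_change >= endpoint.relevance_margin
    else:
        relevant = -observed_change >= endpoint.relevance_margin
    return ResponderCall(
        patient_id=patient_id,
        joint_probability=jp,
        is_responder=jp <= design.responder_cutoff,
        clinically_relevant=bool(relevant),
        observed_change=float(observed_change),
    )


# ---------------------------------------------------------------------------
# Null simulation
# ---------------------------------------------------------------------------


def null_responder_rate(cutoff: float, n_visits: int) -> float:
    """Per-patient probability of a false responder call under the null.

    P(product of ``n_visits`` independent uniforms <= cutoff)
    = cutoff * sum_{j<n_visits} (-ln cutoff)^j / j!.  Equals the cutoff for a
    single visit.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    L = -math.log(cutoff)
    return cutoff * sum(L**j / math.factorial(j) for j in range(n_visits))


def null_joint_probabilities(
    params: ModelParameters,
    n_patients: int,
    future_times: Sequence[float] = (2.0, 4.0, 6.0),
    n_pred_draws: int = 4000,
    seed: int = 0,
    batch_size: int = 250,
    direction: str = "increase",
    method: str = "mc",
) -> np.ndarray:
    """Joint predictive improvement probabilities for null-simulated patients.

    Each patient's effects are drawn from the population of ``params``; the
    held-out future visits and the predictive trajectories both come from the
    same generating law, i.e. the null hypothesis of no treatment effect.

    ``method="mc"`` estimates each orthant probability from ``n_pred_draws``
    predictive trajectories, as in the trial pipeline; ``method="exact"``
    evaluates the analytic predictive (product of per-visit beta tail
    probabilities, exact given the point-mass parameters).
    """
    from scipy.special import betainc

    times = np.asarray(future_times, dtype=float)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(params.population_cov + 1e-12 * np.eye(2))
    nu = params.precision_nu
    out = np.empty(n_patients)
    done = 0
    while done < n_patients:
        nb = min(batch_size, n_patients - done)
        eff = params.population_mean[:, None] + L @ rng.standard_normal((2, nb))
        mu = expit(eff[0][:, None] + eff[1][:, None] * times[None, :])  # (nb, T)
        a, b = mu * nu, (1.0 - mu) * nu
        obs = rng.beta(a, b)
        if method == "exact":
            cdf = betainc(a, b, obs)
            tail = 1.0 - cdf if direction == "increase" else cdf
            out[done : done + nb] = tail.prod(axis=1)
        elif method == "mc":
            pred = rng.beta(a, b, size=(n_pred_draws, nb, times.size))
            if direction == "increase":
                hit = np.all(pred >= obs[None, :, :], axis=2)
            else:
                hit = np.all(pred <= obs[None, :, :], axis=2)
            out[done : done + nb] = hit.mean(axis=0)
        else:
            raise ValueError(f"unknown method {method!r}")
        done += nb
    return out


def simulate_null_counts(
    design: TrialDesign,
    n_trials: int,
    seed: int = 0,
    mode: str = "analytic",
    params: ModelParameters | None = None,
    n_pred_draws: int = 4000,
    future_times: Sequence[float] = (2.0, 4.0, 6.0),
) -> np.ndarray:
    """Responder counts of simulated null trials.

    ``mode="analytic"``: Bernoulli(q) indicators with the analytic null
    responder rate q(cutoff, n_future_visits) — fast.  ``mode="pipeline"``:
    the full per-patient simulation through the predictive machinery (needs
    ``params``); both are seeded and agree in distribution.
    """
    rng = np.random.default_rng(seed)
    if mode == "analytic":
        q = null_responder_rate(design.responder_cutoff, design.n_future_visits)
        return rng.binomial(design.n_patients, q, size=n_trials)
    if mode == "pipeline":
        if params is None:
            raise ValueError("pipeline mode needs generating ModelParameters")
        jp = null_joint_probabilities(
            params,
            n_trials * design.n_patients,
            future_times=tuple(future_times)[: design.n_future_visits],
            n_pred_draws=n_pred_draws,
            seed=seed,
        )
        resp = jp <= design.responder_cutoff
        return resp.reshape(n_trials, design.n_patients).sum(axis=1)
    raise ValueError(f"unknown mode {mode!r}")


def simulate_null_trial(
    params: ModelParameters,
    design: TrialDesign,
    seed: int = 0,
    mode: str = "pipeline",
    **kwargs,
) -> int:
    """Responder count of one simulated null trial."""
    return int(simulate_null_counts(design, 1, seed=seed, mode=mode, params=params, **kwargs)[0])


# ---------------------------------------------------------------------------
# Rate posterior and decision statistic
# ---------------------------------------------------------------------------


def posterior_responder_rate(count: int, n: int, rate_prior=(1.0, 1.0)):
    """Conjugate beta posterior of the responder rate: Beta(a+count, b+n-count)."""
    if not 0 <= count <= n:
        raise ValueError(f"count must be in [0, {n}], got {count}")
    a, b = rate_prior
    return stats.beta(a + count, b + n - count)


class _Degenerate:
    """Point-mass distribution with the frozen-scipy interface we use."""

    def __init__(self, value: float):
        self.value = float(value)

    def rvs(self, size=None, random_state=None):
        return np.full(size, self.value) if size is not None else self.value

    def cdf(self, x):
        return (np.asarray(x, float) >= self.value).astype(float)

    def mean(self):
        return self.value


def fit_null_rate_distribution(
    counts: np.ndarray | None = None,
    n: int | None = None,
    design: TrialDesign | None = None,
    method: str = "moments",
):
    """Reference distribution of the responder rate under no treatment effect.

    ``method="moments"`` (default): a beta distribution fitted by moments to
    the simulated null trial response rates.  ``method="degenerate"``: a point
    mass at the analytic null responder rate.
    """
    if method == "degenerate":
        if design is None:
            raise ValueError("degenerate method needs the design")
        return _Degenerate(null_responder_rate(design.responder_cutoff, design.n_future_visits))
    if method != "moments":
        raise ValueError(f"unknown method {method!r}")
    if counts is None or n is None:
        raise ValueError("moments method needs counts and n")
    r = np.asarray(counts, dtype=float) / n
    m = float(r.mean())
    v = float(r.var(ddof=1))
    if v <= 0 or not 0 < m < 1:
        raise CalibrationError(
            "null rates are degenerate; use method='degenerate' or more trials"
        )
    nu = m * (1.0 - m) / v - 1.0
    if nu <= 0:
        raise CalibrationError("null rate variance exceeds the beta family's range")
    return stats.beta(m * nu, (1.0 - m) * nu)


def prob_rate_difference_positive(
    observed_dist,
    null_dist,
    n_mc: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo P(p_obs - p_null > 0) with independent draws, plus MC SE."""
    rng = np.random.default_rng(seed)
    po = observed_dist.rvs(size=n_mc, random_state=rng)
    pn = null_dist.rvs(size=n_mc, random_state=rng)
    p = float(np.mean(po > pn))
    return p, float(np.sqrt(p * (1.0 - p) / n_mc))


def null_trial_probabilities(
    counts: np.ndarray,
    design: TrialDesign,
    null_dist,
    n_mc: int = 200_000,
    seed: int = 0,
) -> np.ndarray:
    """Decision statistic for every simulated trial.

    The statistic depends on a trial only through its responder count, so it
    is computed once per distinct count (shared Monte-Carlo draws of the null
    rate) and broadcast.
    """
    counts = np.asarray(counts)
    rng = np.random.default_rng(seed)
    pn = null_dist.rvs(size=n_mc, random_state=rng)
    lut = {}
    for k in np.unique(counts):
        post = posterior_responder_rate(int(k), design.n_patients, design.rate_prior)
        po = post.rvs(size=n_mc, random_state=rng)
        lut[int(k)] = float(np.mean(po > pn))
    return np.array([lut[int(k)] for k in counts])


# ---------------------------------------------------------------------------
# Calibration and assurance
# ---------------------------------------------------------------------------


def calibrate_threshold(
    null_probabilities: np.ndarray,
    alpha: float = 0.05,
    grid_step: float = 0.01,
) -> float:
    """Smallest grid threshold c with null rejection rate P(prob > c) <= alpha.

    The declared trial rule is "success iff probability > c".  Ties on the
    grid resolve toward the larger (more conservative) threshold by the
    strict-inequality rejection rule itself.
    """
    probs = np.asarray(null_probabilities, dtype=float)
    if probs.size < 1000:
        raise ValueError("calibration needs >= 1000 null trial simulations")
    grid = np.round(np.arange(0.0, 1.0, grid_step), 10)
    rates = np.array([(probs > c).mean() for c in grid])
    ok = rates <= alpha
    if not ok.any():
        raise CalibrationError(
            f"no grid threshold attains alpha={alpha}; achievable minimum is "
            f"{rates.min():.4f} at c={grid[-1]:.2f}"
        )
    return float(grid[np.argmax(ok)])


@dataclass
class NullCalibration:
    """Everything produced by calibrating a design on null simulations."""

    design: TrialDesign
    counts: np.ndarray
    null_rate_dist: object
    probabilities: np.ndarray
    threshold: float
    type1_on_calibration: float
    n_trials: int
    seed: int

    @property
    def calibrated_design(self) -> TrialDesign:
        return replace(self.design, decision_threshold=self.threshold)


def calibrate_design(
    design: TrialDesign,
    n_trials: int = 10_000,
    seed: int = 0,
    n_mc: int = 200_000,
    mode: str = "analytic",
    params: ModelParameters | None = None,
    null_rate_method: str = "moments",
) -> NullCalibration:
    """Simulate null trials, fit the null rate distribution, and calibrate the
    decision threshold to the design's overall Type I bound."""
    ss = np.random.SeedSequence(seed).spawn(2)
    counts = simulate_null_counts(
        design, n_trials, seed=ss[0].generate_state(1)[0] % 2**31, mode=mode, params=params
    )
    if null_rate_method == "moments":
        null_dist = fit_null_rate_distribution(counts, design.n_patients, method="moments")
    else:
        null_dist = fit_null_rate_distribution(design=design, method="degenerate")
    probs = null_trial_probabilities(
        counts, design, null_dist, n_mc=n_mc, seed=ss[1].generate_state(1)[0] % 2**31
    )
    c = calibrate_threshold(probs, design.alpha)
    return NullCalibration(
        design=design,
        counts=counts,
        null_rate_dist=null_dist,
        probabilities=probs,
        threshold=c,
        type1_on_calibration=float((probs > c).mean()),
        n_trials=n_trials,
        seed=seed,
    )


def estimate_type1(
    calibration: NullCalibration,
    n_trials: int = 10_000,
    seed: int = 1,
    n_mc: int = 200_000,
    mode: str = "analytic",
    params: ModelParameters | None = None,
) -> float:
    """Rejection rate of the calibrated rule on fresh null simulations."""
    design = calibration.design
    ss = np.random.SeedSequence(seed).spawn(2)
    counts = simulate_null_counts(
        design, n_trials, seed=ss[0].generate_state(1)[0] % 2**31, mode=mode, params=params
    )
    probs = null_trial_probabilities(
        counts,
        design,
        calibration.null_rate_dist,
        n_mc=n_mc,
        seed=ss[1].generate_state(1)[0] % 2**31,
    )
    return float((probs > calibration.threshold).mean())


def assurance_curve(
    design: TrialDesign,
    deltas: Sequence[float] = tuple(np.round(np.arange(0.0, 0.85, 0.05), 2)),
    n_sim: int = 10_000,
    seed: int = 0,
    n_patients_set: Sequence[int] = (12, 24),
    n_mc: int = 200_000,
) -> TrialOperatingCharacteristics:
    """Assurance (expected power) against the increase in responder rate.

    For each sample size, the decision threshold is calibrated on null
    simulations of that size, then trials are simulated with responder
    probability (null rate + delta) and the success fraction recorded.  The
    point at delta = 0 is the design's Type I error estimate.  These
    operating characteristics depend on the endpoint only through the
    responder definition, so they hold for any endpoint measure.
    """
    deltas = np.asarray(list(deltas), dtype=float)
    q0 = null_responder_rate(design.responder_cutoff, design.n_future_visits)
    rows = []
    type1 = threshold = None
    for j, n_pat in enumerate(n_patients_set):
        d_n = replace(design, n_patients=int(n_pat))
        cal = calibrate_design(d_n, n_trials=n_sim, seed=seed + 17 * j, n_mc=n_mc)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 101 + j]).generate_state(1)[0] % 2**31)
        # decision statistic depends on a trial only through its count
        prob_by_count = null_trial_probabilities(
            np.arange(n_pat + 1), d_n, cal.null_rate_dist, n_mc=n_mc, seed=seed + 1000 + j
        )
        for delta in deltas:
            p = q0 + float(delta)
            if p > 1.0:
                warnings.warn(
                    f"responder rate {p:.3f} clipped to 1 at delta={delta}", RuntimeWarning
                )
                p = 1.0
            counts = rng.binomial(n_pat, p, size=n_sim)
            power = float((prob_by_count[counts] > cal.threshold).mean())
            rows.append({"delta": float(delta), "n": int(n_pat), "power": power})
            if n_pat == design.n_patients and delta == 0.0:
                type1 = power
        if n_pat == design.n_patients:
            threshold = cal.threshold
    if threshold is None:
        # design.n_patients not in the requested set: calibrate it explicitly
        cal = calibrate_design(design, n_trials=n_sim, seed=seed, n_mc=n_mc)
        threshold = cal.threshold
        type1 = cal.type1_on_calibration
    return TrialOperatingCharacteristics(
        type1_error=float(type1),
        calibrated_threshold=float(threshold),
        assurance=pd.DataFrame(rows),
        n_sim=n_sim,
        seed=seed,
    )
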
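"""Tests for responder calling, null calibration and assurance."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import betainc

import betaprog as bp
from betaprog import trial_engine as te

FEV1 = bp.ENDPOINTS["fev1_pct"]
DESIGN = bp.TrialDesign()


# ---------------------------------------------------------------------------
# responder calling
# ---------------------------------------------------------------------------


def test_responder_cutoff_is_inclusive():
    assert te.call_responder(0.01, 0.0, DESIGN, FEV1).is_responder
    assert not te.call_responder(0.011, 0.0, DESIGN, FEV1).is_responder


def test_clinical_relevance_margin():
    # +9 FEV1 points against a margin of 8
    assert te.call_responder(0.5, 9.0, DESIGN, FEV1).clinically_relevant
    assert not te.call_responder(0.001, 7.9, DESIGN, FEV1).clinically_relevant
    vent = bp.ENDPOINTS["ventilator_hours"]
    vent8 = replace(vent, relevance_margin=2.0)
    assert te.call_responder(0.5, -3.0, DESIGN, vent8).clinically_relevant
    assert not te.call_responder(0.5, 3.0, DESIGN, vent8).clinically_relevant


# ---------------------------------------------------------------------------
# null responder rate and null trials
# ---------------------------------------------------------------------------


def test_null_responder_rate_single_visit_equals_cutoff():
    assert te.null_responder_rate(0.01, 1) == pytest.approx(0.01)


def test_null_responder_rate_matches_product_of_uniforms_oracle():
    rng = np.random.default_rng(0)
    u = rng.random((1_000_000, 3)).prod(axis=1)
    mc = float(np.mean(u <= 0.01))
    se = np.sqrt(mc * (1 - mc) / u.size)
    assert te.null_responder_rate(0.01, 3) == pytest.approx(mc, abs=3 * se)


def test_shortcut_binomial_identities():
    """For a single future visit the shortcut is Bernoulli(cutoff):
    P(count >= 1) = 1 - 0.99^12 and E[count] = 0.12."""
    design = replace(DESIGN, n_future_visits=1)
    counts = te.simulate_null_counts(design, 200_000, seed=3)
    p_any = float(np.mean(counts >= 1))
    exact = 1.0 - 0.99**12
    assert exact == pytest.approx(0.1136, abs=5e-4)
    assert p_any == pytest.approx(exact, abs=3 * np.sqrt(exact * (1 - exact) / counts.size))
    assert counts.mean() == pytest.approx(0.12, abs=0.01)


def test_full_pipeline_agrees_with_analytic_shortcut(default_params):
    """Per-patient simulation through the predictive machinery reproduces the
    analytic Bernoulli(q) shortcut."""
    n_trials = 300
    full = te.simulate_null_counts(
        DESIGN, n_trials, seed=4, mode="pipeline", params=default_params, n_pred_draws=2000
    )
    q = te.null_responder_rate(DESIGN.responder_cutoff, DESIGN.n_future_visits)
    se = np.sqrt(12 * q * (1 - q) / n_trials)
    assert full.mean() == pytest.approx(12 * q, abs=3 * se)


def test_simulate_null_trial_single(default_params):
    k = te.simulate_null_trial(default_params, DESIGN, seed=0, n_pred_draws=1000)
    assert 0 <= k <= DESIGN.n_patients


# ---------------------------------------------------------------------------
# rate posterior and decision statistic
# ---------------------------------------------------------------------------


def test_posterior_responder_rate_conjugacy():
    post = te.posterior_responder_rate(3, 12, (1.0, 1.0))
    a, b = post.args
    assert (a, b) == (4.0, 10.0)
    assert post.mean() == pytest.approx(4 / 14)
    zero = te.posterior_responder_rate(0, 12, (1.0, 1.0))
    assert zero.args == (1.0, 13.0)


def test_posterior_mean_between_prior_mean_and_mle():
    prior = (2.0, 6.0)  # prior mean 0.25
    post = te.posterior_responder_rate(9, 12, prior)  # mle 0.75
    assert 0.25 < post.mean() < 0.75


def test_prob_rate_difference_symmetry():
    d = stats.beta(4, 10)
    p, se = te.prob_rate_difference_positive(d, stats.beta(4, 10), n_mc=100_000, seed=0)
    assert p == pytest.approx(0.5, abs=3 * se)


def test_prob_rate_difference_degenerate_null_incomplete_beta_oracle():
    obs = stats.beta(4, 10)
    null = te._Degenerate(0.01)
    p, se = te.prob_rate_difference_positive(obs, null, n_mc=200_000, seed=1)
    oracle = 1.0 - betainc(4, 10, 0.01)  # independent incomplete-beta CDF
    assert p == pytest.approx(oracle, abs=3 * se + 1e-4)


def test_prob_rate_difference_stochastic_dominance():
    p, _ = te.prob_rate_difference_positive(stats.beta(2, 20), stats.beta(20, 2), n_mc=50_000, seed=2)
    assert p < 0.5


# ---------------------------------------------------------------------------
# threshold calibration
# ---------------------------------------------------------------------------


def test_calibrate_threshold_degenerate_alpha_one():
    probs = np.linspace(0.01, 0.99, 2000)
    assert te.calibrate_threshold(probs, alpha=1.0) == 0.0


def test_calibrate_threshold_requires_enough_simulations():
    with pytest.raises(ValueError, match=">= 1000"):
        te.calibrate_threshold(np.array([0.5, 0.6]), alpha=0.05)


def test_calibrate_threshold_unattainable_bound():
    with pytest.raises(te.CalibrationError, match="achievable minimum"):
        te.calibrate_threshold(np.full(2000, 0.9999), alpha=0.05)


def _enumeration_oracle(design, null_dist):
    """Exhaustive enumeration over responder counts with exact binomial
    weights and quadrature for the decision statistic."""
    n = design.n_patients
    q = te.null_responder_rate(design.responder_cutoff, design.n_future_visits)
    w = stats.binom.pmf(np.arange(n + 1), n, q)
    a0, b0 = null_dist.args
    pk = []
    for k in range(n + 1):
        post = te.posterior_responder_rate(k, n, design.rate_prior)
        f = lambda p: post.pdf(p) * stats.beta.cdf(p, a0, b0)
        pk.append(integrate.quad(f, 0, 1, limit=400)[0])
    pk = np.array(pk)
    grid = np.round(np.arange(0.0, 1.0, 0.01), 10)
    for c in grid:
        if float(w[pk > c].sum()) <= design.alpha:
            return float(c)
    raise AssertionError("oracle found no threshold")


@pytest.mark.parametrize("n_visits", [1, 3])
def test_calibration_agrees_with_enumeration_oracle(n_visits):
    """Monte-Carlo calibration vs exhaustive Binomial enumeration on the toy
    model where responder indicators are exactly Bernoulli."""
    design = replace(DESIGN, n_future_visits=n_visits)
    cal = te.calibrate_design(design, n_trials=20_000, seed=8)
    oracle = _enumeration_oracle(design, cal.null_rate_dist)
    assert cal.threshold == oracle


def test_calibrate_design_deterministic():
    a = te.calibrate_design(DESIGN, n_trials=5000, seed=5)
    b = te.calibrate_design(DESIGN, n_trials=5000, seed=5)
    assert a.threshold == b.threshold
    assert np.array_equal(a.probabilities, b.probabilities)


def test_fit_null_rate_distribution_moments_and_degenerate():
    counts = te.simulate_null_counts(DESIGN, 20_000, seed=6)
    fitted = te.fit_null_rate_distribution(counts, DESIGN.n_patients)
    r = counts / DESIGN.n_patients
    assert fitted.mean() == pytest.approx(r.mean(), rel=1e-6)
    assert fitted.var() == pytest.approx(r.var(ddof=1), rel=1e-6)
    point = te.fit_null_rate_distribution(design=DESIGN, method="degenerate")
    assert point.mean() == pytest.approx(te.null_responder_rate(0.01, 3))
    with pytest.raises(te.CalibrationError):
        te.fit_null_rate_distribution(np.zeros(2000, dtype=int), DESIGN.n_patients)


def test_fresh_type1_at_or_below_alpha():
    cal = te.calibrate_design(DESIGN, n_trials=10_000, seed=9)
    t1 = te.estimate_type1(cal, n_trials=10_000, seed=10)
    se = np.sqrt(DESIGN.alpha * (1 - DESIGN.alpha) / 10_000)
    assert t1 <= DESIGN.alpha + 3 * se


# ---------------------------------------------------------------------------
# assurance
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def operating_characteristics():
    return te.assurance_curve(DESIGN, n_sim=10_000, seed=12)


def test_assurance_monotone_and_saturating(operating_characteristics):
    curve = operating_characteristics.assurance
    for n, grp in curve.groupby("n"):
        power = grp.sort_values("delta")["power"].to_numpy()
        assert np.all(np.diff(power) >= -0.02)  # MC tolerance
        assert power[-1] > 0.99


def test_larger_trial_dominates(operating_characteristics):
    wide = operating_characteristics.assurance.pivot(index="delta", columns="n", values="power")
    assert np.all(wide[24].to_numpy() >= wide[12].to_numpy() - 0.02)


def test_assurance_at_zero_is_type1(operating_characteristics):
    curve = operating_characteristics.assurance
    at_zero = curve[(curve["delta"] == 0.0) & (curve["n"] == DESIGN.n_patients)]["power"].iloc[0]
    assert at_zero == operating_characteristics.type1_error
    assert operating_characteristics.type1_error <= DESIGN.alpha


def test_assurance_clips_impossible_rates():
    with pytest.warns(RuntimeWarning, match="clipped"):
        te.assurance_curve(DESIGN, deltas=[0.0, 0.99], n_sim=2000, seed=1, n_patients_set=(12,))


def test_assurance_independent_of_endpoint_identity(operating_characteristics):
    """Operating characteristics depend only on responder probabilities, not
    on which endpoint defines the responders: same seeds, same curve."""
    again = te.assurance_curve(DESIGN, n_sim=10_000, seed=12)
    assert again.assurance.equals(operating_characteristics.assurance)
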
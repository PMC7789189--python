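"""Unit and property tests for the beta/logit progression model core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import betaprog as bp
from betaprog.core_model import (
    ENDPOINTS,
    EndpointSpec,
    LongitudinalDataset,
    Observation,
    PatientMeta,
    beta_logpdf,
    beta_shape,
    log_likelihood,
    logit_mean,
    posterior_fit_check,
    scale_score,
    unscale_score,
)

FEV1 = ENDPOINTS["fev1_pct"]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(lower_bound=10, upper_bound=10),
        dict(lower_bound=10, upper_bound=5),
        dict(relevance_margin=-1),
        dict(improvement_direction="sideways"),
    ],
)
def test_endpoint_spec_rejects_invalid(kwargs):
    base = dict(name="x", lower_bound=0.0, upper_bound=100.0)
    with pytest.raises(ValueError):
        EndpointSpec(**{**base, **kwargs})


def test_observation_rejects_boundary_and_negative_time():
    with pytest.raises(ValueError):
        Observation("p", 0.0, 5.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        Observation("p", -1.0, 5.0, 50.0, 0.5)


def test_dataset_requires_observations_per_patient(fev1):
    obs = [Observation("a", 0.0, 5.0, 50.0, 0.5)]
    with pytest.raises(ValueError, match="without observations"):
        LongitudinalDataset(fev1, obs, {"a": PatientMeta("a"), "b": PatientMeta("b")})


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------


def test_scale_score_midpoint_is_half_for_any_squeeze():
    assert scale_score(50.0, FEV1, n_obs=295) == pytest.approx(0.5)


def test_scale_score_boundary_squeeze():
    s = scale_score(100.0, FEV1, n_obs=59 * 5)
    assert 0.99 < s < 1.0
    s0 = scale_score(0.0, FEV1, n_obs=59 * 5)
    assert 0.0 < s0 < 0.01


def test_scale_unscale_round_trip():
    x = 37.2
    assert unscale_score(scale_score(x, FEV1, 295), FEV1, 295) == pytest.approx(x, abs=1e-10)


def test_scale_score_out_of_bounds_names_context():
    with pytest.raises(ValueError, match="patient P7"):
        scale_score(101.0, FEV1, 10, context="patient P7")


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    raw=st.floats(0.0, 24.0),
    n_obs=st.integers(2, 5000),  # with a single observation the squeeze is constant
)
def test_scale_score_interior_and_invertible(raw, n_obs):
    vent = ENDPOINTS["ventilator_hours"]
    s = scale_score(raw, vent, n_obs)
    assert 0.0 < s < 1.0
    assert unscale_score(s, vent, n_obs) == pytest.approx(raw, abs=1e-8)


# ---------------------------------------------------------------------------
# link and likelihood
# ---------------------------------------------------------------------------


def test_logit_mean_closed_forms():
    assert logit_mean(0.0, 0.0, T=5.0, t=3.0) == pytest.approx(0.5)
    assert logit_mean(np.log(3.0), 0.0, T=0.0, t=12.0) == pytest.approx(0.75)
    # centering: chi = 0 when T + t = 0
    assert logit_mean(0.0, 0.1, T=-10.0, t=10.0) == pytest.approx(0.5)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    alpha=st.floats(-5, 5),
    beta=st.floats(-0.2, 0.2),
    t=st.floats(0, 48),
    eps=st.floats(0.01, 2.0),
)
def test_logit_mean_monotonicity(alpha, beta, t, eps):
    base = logit_mean(alpha, beta, 0.0, t)
    assert 0.0 < base < 1.0
    assert logit_mean(alpha + eps, beta, 0.0, t) > base
    later = logit_mean(alpha, beta, 0.0, t + 1.0)
    if beta > 1e-12:
        assert later > base
    elif beta < -1e-12:
        assert later < base


def test_beta_shape_examples():
    assert beta_shape(0.5, 10.0) == pytest.approx((5.0, 5.0))
    assert beta_shape(0.8, 20.0) == pytest.approx((16.0, 4.0))
    with pytest.raises(ValueError):
        beta_shape(1.0, 10.0)
    with pytest.raises(ValueError):
        beta_shape(0.5, 0.0)


def test_beta_shape_moment_identities():
    """E[y] = mu and Var[y] = mu(1-mu)/(1+nu), checked by Monte Carlo."""
    mu, nu = 0.5, 10.0
    a, b = beta_shape(mu, nu)
    rng = np.random.default_rng(0)
    y = rng.beta(a, b, size=200_000)
    var = mu * (1 - mu) / (1 + nu)
    assert var == pytest.approx(0.25 / 11, abs=1e-12)
    assert y.mean() == pytest.approx(mu, abs=4 * np.sqrt(var / y.size))
    assert y.var() == pytest.approx(var, rel=0.02)


def _one_patient_dataset(y, times, endpoint=FEV1):
    obs = [
        Observation("p1", float(t), 10.0, endpoint.lower_bound + v * endpoint.span, float(v))
        for t, v in zip(times, y)
    ]
    return LongitudinalDataset(endpoint, obs, {"p1": PatientMeta("p1")}, 0.0)


def _params(effects, nu):
    return bp.ModelParameters(0.0, 0.0, 1.0, 0.01, 0.0, nu, effects)


def test_log_likelihood_uniform_case_is_zero():
    # alpha=0, beta=0, nu=2 -> Beta(1, 1), density 1 everywhere
    ds = _one_patient_dataset([0.5], [0.0])
    assert log_likelihood(ds, _params({"p1": (0.0, 0.0)}, 2.0)) == pytest.approx(0.0, abs=1e-12)


def test_log_likelihood_additivity():
    one = _one_patient_dataset([0.37], [0.0])
    two = _one_patient_dataset([0.37, 0.37], [0.0, 0.0])
    p = _params({"p1": (0.4, -0.01)}, 30.0)
    assert log_likelihood(two, p) == pytest.approx(2 * log_likelihood(one, p), abs=1e-10)


def test_log_likelihood_matches_generic_beta_density_oracle():
    """Hand-written likelihood vs scipy's beta.logpdf on random configurations."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = rng.integers(2, 8)
        times = np.sort(rng.uniform(0, 36, n))
        y = rng.uniform(0.05, 0.95, n)
        alpha, beta, nu = rng.normal(0, 1), rng.normal(0, 0.02), rng.uniform(2, 150)
        ds = _one_patient_dataset(y, times)
        ours = log_likelihood(ds, _params({"p1": (alpha, beta)}, nu))
        mu = 1 / (1 + np.exp(-(alpha + beta * times)))
        oracle = stats.beta.logpdf(y, mu * nu, (1 - mu) * nu).sum()
        assert ours == pytest.approx(oracle, abs=1e-10)


def test_log_likelihood_missing_patient_effect():
    ds = _one_patient_dataset([0.5], [0.0])
    with pytest.raises(KeyError, match="p1"):
        log_likelihood(ds, _params({"someone_else": (0.0, 0.0)}, 2.0))


# ---------------------------------------------------------------------------
# MCMC contracts
# ---------------------------------------------------------------------------


def test_fit_is_seed_deterministic(small_cohort):
    kw = dict(n_chains=2, n_iter=150, n_warmup=150)
    d1 = bp.fit_mcmc(small_cohort, seed=3, **kw)
    d2 = bp.fit_mcmc(small_cohort, seed=3, **kw)
    assert np.array_equal(d1.pop_intercept, d2.pop_intercept)
    assert np.array_equal(d1.alpha, d2.alpha)
    assert d1.summary().equals(d2.summary())


def test_fit_single_patient_two_visits_runs_wide():
    ds = _one_patient_dataset([0.55, 0.5], [0.0, 6.0])
    draws = bp.fit_mcmc(ds, n_chains=2, n_iter=200, n_warmup=200, seed=1)
    # prior-dominated: random-effect scale posterior stays wide
    assert draws.flat("re_sd_intercept").mean() > 0.5
    assert draws.alpha.shape[-1] == 1


def test_fit_flags_nonconvergence():
    ds = _one_patient_dataset([0.5, 0.52, 0.48], [0.0, 3.0, 6.0])
    with pytest.warns(RuntimeWarning):
        draws = bp.fit_mcmc(ds, n_chains=2, n_iter=40, n_warmup=40, seed=0)
    assert not draws.converged
    assert draws.warnings_


def test_posterior_draws_save_load_round_trip(tmp_path, small_fit):
    path = tmp_path / "post.npz"
    small_fit.save(path)
    back = bp.PosteriorDraws.load(path)
    assert np.array_equal(back.alpha, small_fit.alpha)
    assert back.patient_ids == small_fit.patient_ids
    assert back.endpoint == small_fit.endpoint
    assert back.seed == small_fit.seed


def test_posterior_fit_check(small_fit, small_cohort):
    check = posterior_fit_check(small_fit, small_cohort, level=0.95, seed=0)
    assert 0.0 <= check.coverage <= 1.0
    # reduced fit on a correctly specified model should still cover most points
    assert check.coverage > 0.8
    assert len(check.fitted) == len(small_cohort)
    assert (check.fitted["pi_lower"] <= check.fitted["pi_upper"]).all()


def test_posterior_fit_check_endpoint_mismatch(small_fit, small_cohort):
    other = bp.CohortConfig(
        n_mtm1=2,
        n_dnm2=0,
        age_stratum_counts={"0-2": 0, "2-6": 0, "6-16": 1, ">16": 1},
        endpoint=ENDPOINTS["ventilator_hours"],
        seed=0,
    )
    with pytest.raises(ValueError, match="endpoint mismatch"):
        posterior_fit_check(small_fit, bp.simulate_cohort(other))


def test_fitted_trajectories_monotone_per_draw(small_fit):
    """chi is exactly linear in t, so each draw's mean trajectory is monotone
    with the sign of that draw's slope."""
    t = np.array([0.0, 6.0, 12.0, 24.0])
    al = small_fit.flat("alpha")[:50, 0]
    be = small_fit.flat("beta")[:50, 0]
    mu = 1 / (1 + np.exp(-(al[:, None] + be[:, None] * t[None, :])))
    diffs = np.diff(mu, axis=1)
    assert np.all(np.sign(diffs) == np.sign(be)[:, None])
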
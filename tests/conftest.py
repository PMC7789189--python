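import numpy as np
import pytest

import betaprog as bp


@pytest.fixture(scope="session")
def default_params() -> bp.ModelParameters:
    return bp.default_generating_parameters()


@pytest.fixture(scope="session")
def small_cohort() -> bp.LongitudinalDataset:
    """A 24-patient cohort drawn from the default generating model."""
    cfg = bp.CohortConfig(
        n_mtm1=18,
        n_dnm2=6,
        age_stratum_counts={"0-2": 4, "2-6": 4, "6-16": 6, ">16": 10},
        seed=42,
    )
    return bp.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_fit(small_cohort) -> bp.PosteriorDraws:
    """A reduced-size MCMC fit shared by tests that need a real posterior."""
    return bp.fit_mcmc(small_cohort, n_chains=2, n_iter=800, n_warmup=500, seed=11)


@pytest.fixture()
def fev1() -> bp.EndpointSpec:
    return bp.ENDPOINTS["fev1_pct"]


@pytest.fixture()
def point_mass_draws(fev1):
    """Point-mass 'posterior' helper: predictive equals the generating law."""

    def make(alpha=0.0, beta=0.0, nu=2.0, n_draws=3000, patient="A"):
        params = bp.ModelParameters(
            pop_intercept_mean=alpha,
            pop_slope_mean=beta,
            re_sd_intercept=0.8,
            re_sd_slope=0.01,
            re_correlation=0.0,
            precision_nu=nu,
            patient_effects={patient: (alpha, beta)},
        )
        return bp.PosteriorDraws.from_parameters(params, fev1, n_draws=n_draws)

    return make
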
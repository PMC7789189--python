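"""Adaptive Metropolis-within-Gibbs sampler for the beta/logit mixed model.

The model factorizes conveniently: given the population block, the per-patient
random effects are conditionally independent, so all patients are updated in
parallel with vectorized Metropolis steps; the population mean is conjugate
normal given the effects and covariance; the covariance block (two log-sds and
an atanh-correlation) and log(nu) use adaptive random-walk Metropolis.

Proposal scales adapt only during warmup (Robbins-Monro on acceptance rates,
plus an empirical proposal covariance for the 3-d covariance block) and are
frozen afterwards, so the retained draws come from valid Markov chains.

Internally time is re-centred at the mean observation time, which largely
decorrelates intercepts and slopes; draws are mapped back to the dataset's
parameterization ``chi = alpha + beta * (T + t)`` before being returned.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, logit

from .core_model import LongitudinalDataset, PosteriorDraws, PriorSpec

_TARGET_1D = 0.44  # optimal RW acceptance, one-dimensional updates
_TARGET_BLOCK = 0.30


def _beta_loglik_obs(chi: np.ndarray, nu: float, logy, log1my) -> np.ndarray:
    mu = expit(chi)
    a = mu * nu
    b = (1.0 - mu) * nu
    return (a - 1.0) * logy + (b - 1.0) * log1my - betaln(a, b)


def _bvn_logpdf(a, b, m, sa, sb, rho):
    """Bivariate normal log-density of points (a, b), elementwise."""
    za = (a - m[0]) / sa
    zb = (b - m[1]) / sb
    om = 1.0 - rho * rho
    return (
        -0.5 * (za * za - 2.0 * rho * za * zb + zb * zb) / om
        - np.log(sa)
        - np.log(sb)
        - 0.5 * np.log(om)
        - np.log(2.0 * np.pi)
    )


def _cov_block_logprior(lsa, lsb, zr, priors: PriorSpec):
    # half-normal on each sd, parameterized on the log scale (+ Jacobian);
    # correlation uniform on [-1, 1] via atanh (+ Jacobian log(1 - rho^2))
    sa, sb = np.exp(lsa), np.exp(lsb)
    s0 = priors.re_sd_scale
    rho = np.tanh(zr)
    return (
        -0.5 * (sa * sa + sb * sb) / (s0 * s0)
        + lsa
        + lsb
        + np.log1p(-rho * rho)
    )


def _init_state(y, tc, idx, n_pat, starts, counts, rng):
    """Empirical initialization: per-patient logit regressions plus jitter."""
    z = logit(y)
    a0 = np.empty(n_pat)
    b0 = np.empty(n_pat)
    for i in range(n_pat):
        sl = slice(starts[i], starts[i] + counts[i])
        zi, ti = z[sl], tc[sl]
        if counts[i] >= 2 and np.ptp(ti) > 0:
            vb = np.cov(ti, zi)
            slope = vb[0, 1] / vb[0, 0]
        else:
            slope = 0.0
        slope = float(np.clip(slope, -0.2, 0.2))
        b0[i] = slope
        a0[i] = zi.mean() - slope * ti.mean()
    a = a0 + 0.1 * rng.standard_normal(n_pat)
    b = b0 + 0.005 * rng.standard_normal(n_pat)
    m = np.array([a.mean(), b.mean()]) + rng.normal(0, [0.05, 0.002])
    lsa = np.log(max(np.std(a0), 0.05)) + 0.2 * rng.standard_normal()
    lsb = np.log(max(np.std(b0), 0.002)) + 0.2 * rng.standard_normal()
    zr = 0.2 * rng.standard_normal()
    mu0 = expit(a[idx] + b[idx] * tc)
    v = max(float(np.mean((y - mu0) ** 2)), 1e-4)
    nu0 = float(np.clip(np.mean(mu0 * (1.0 - mu0)) / v - 1.0, 2.0, 500.0))
    lnu = np.log(nu0) + 0.3 * rng.standard_normal()
    return a, b, m, lsa, lsb, zr, lnu


def _run_chain(y, tc, idx, starts, counts, n_pat, priors, n_warmup, n_draws, rng):
    logy, log1my = np.log(y), np.log1p(-y)

    def perpat_ll(a, b, nu):
        chi = a[idx] + b[idx] * tc
        return np.add.reduceat(_beta_loglik_obs(chi, nu, logy, log1my), starts)

    a, b, m, lsa, lsb, zr, lnu = _init_state(y, tc, idx, n_pat, starts, counts, rng)
    nu = float(np.exp(lnu))
    ll = perpat_ll(a, b, nu)

    # proposal scales
    s_a = 1.0 / np.sqrt(np.maximum(counts, 1.0))
    s_b = np.full(n_pat, 0.01)
    s_cov = 0.3
    s_cov2 = 0.3
    L_cov = np.eye(3) * np.array([0.3, 0.3, 0.3])
    s_nu = 0.3

    # prior precision for the conjugate population-mean update
    p0_prec = np.diag([priors.intercept_scale**-2, priors.slope_scale**-2])
    p0_loc = np.array([priors.intercept_loc, priors.slope_loc])

    theta_hist = np.empty((n_warmup, 3))

    out_a = np.empty((n_draws, n_pat))
    out_b = np.empty((n_draws, n_pat))
    out_m = np.empty((n_draws, 2))
    out_cov = np.empty((n_draws, 3))  # sd_a, sd_b, rho
    out_nu = np.empty(n_draws)

    for it in range(n_warmup + n_draws):
        warm = it < n_warmup
        gamma = (it + 10.0) ** -0.6 if warm else 0.0
        sa, sb, rho = np.exp(lsa), np.exp(lsb), np.tanh(zr)

        # --- per-patient intercepts (parallel Metropolis) ---
        prop = a + s_a * rng.standard_normal(n_pat)
        llp = perpat_ll(prop, b, nu)
        dprior = _bvn_logpdf(prop, b, m, sa, sb, rho) - _bvn_logpdf(a, b, m, sa, sb, rho)
        acc = np.log(rng.random(n_pat)) < (llp - ll + dprior)
        a = np.where(acc, prop, a)
        ll = np.where(acc, llp, ll)
        if warm:
            s_a *= np.exp(gamma * (acc - _TARGET_1D))

        # --- per-patient slopes ---
        prop = b + s_b * rng.standard_normal(n_pat)
        llp = perpat_ll(a, prop, nu)
        dprior = _bvn_logpdf(a, prop, m, sa, sb, rho) - _bvn_logpdf(a, b, m, sa, sb, rho)
        acc = np.log(rng.random(n_pat)) < (llp - ll + dprior)
        b = np.where(acc, prop, b)
        ll = np.where(acc, llp, ll)
        if warm:
            s_b *= np.exp(gamma * (acc - _TARGET_1D))

        # --- population mean: conjugate normal given effects and covariance ---
        cov = np.array([[sa * sa, rho * sa * sb], [rho * sa * sb, sb * sb]])
        cov_inv = np.linalg.inv(cov)
        post_prec = n_pat * cov_inv + p0_prec
        post_cov = np.linalg.inv(post_prec)
        post_mean = post_cov @ (cov_inv @ np.array([a.sum(), b.sum()]) + p0_prec @ p0_loc)
        m = post_mean + np.linalg.cholesky(post_cov) @ rng.standard_normal(2)

        # --- random-effect covariance block (3-d adaptive Metropolis) ---
        theta = np.array([lsa, lsb, zr])
        cur = float(np.sum(_bvn_logpdf(a, b, m, sa, sb, rho))) + float(
            _cov_block_logprior(lsa, lsb, zr, priors)
        )
        propt = theta + s_cov * (L_cov @ rng.standard_normal(3))
        sap, sbp, rhop = np.exp(propt[0]), np.exp(propt[1]), np.tanh(propt[2])
        new = float(np.sum(_bvn_logpdf(a, b, m, sap, sbp, rhop))) + float(
            _cov_block_logprior(propt[0], propt[1], propt[2], priors)
        )
        acc_cov = np.log(rng.random()) < new - cur
        if acc_cov:
            lsa, lsb, zr = propt
        if warm:
            theta_hist[it] = (lsa, lsb, zr)
            s_cov *= np.exp(gamma * (acc_cov - _TARGET_BLOCK))
            if it >= 100 and it % 25 == 0:
                emp = np.cov(theta_hist[max(0, it - 500) : it + 1].T) + 1e-8 * np.eye(3)
                L_cov = np.linalg.cholesky(emp * (2.38**2 / 3.0))

        # --- covariance block again, non-centred (ASIS interleaving) ---
        # re-express effects as standardized residuals Z, move the scales
        # jointly with the effects; escapes the centred-frame funnel.
        sa, sb, rho = np.exp(lsa), np.exp(lsb), np.tanh(zr)
        l11, l21, l22 = sa, rho * sb, sb * np.sqrt(max(1.0 - rho * rho, 1e-12))
        z1 = (a - m[0]) / l11
        z2 = (b - m[1] - l21 * z1) / l22
        theta = np.array([lsa, lsb, zr])
        propt = theta + s_cov2 * (L_cov @ rng.standard_normal(3))
        sap, sbp, rhop = np.exp(propt[0]), np.exp(propt[1]), np.tanh(propt[2])
        l22p = sbp * np.sqrt(max(1.0 - rhop * rhop, 1e-12))
        ap = m[0] + sap * z1
        bp_ = m[1] + rhop * sbp * z1 + l22p * z2
        llp = perpat_ll(ap, bp_, nu)
        dprior = _cov_block_logprior(propt[0], propt[1], propt[2], priors) - _cov_block_logprior(
            lsa, lsb, zr, priors
        )
        acc_nc = np.log(rng.random()) < float(llp.sum() - ll.sum()) + float(dprior)
        if acc_nc:
            lsa, lsb, zr = propt
            a, b, ll = ap, bp_, llp
        if warm:
            s_cov2 *= np.exp(gamma * (acc_nc - _TARGET_BLOCK))

        # --- precision nu (1-d adaptive Metropolis on the log scale) ---
        lnup = lnu + s_nu * rng.standard_normal()
        nup = float(np.exp(lnup))
        llnup = perpat_ll(a, b, nup)
        dprior = (lnup - priors.log_nu_loc) ** 2 - (lnu - priors.log_nu_loc) ** 2
        dprior *= -0.5 / priors.log_nu_scale**2
        acc_nu = np.log(rng.random()) < float(llnup.sum() - ll.sum()) + dprior
        if acc_nu:
            lnu, nu, ll = lnup, nup, llnup
        if warm:
            s_nu *= np.exp(gamma * (acc_nu - _TARGET_1D))

        if not warm:
            j = it - n_warmup
            out_a[j] = a
            out_b[j] = b
            out_m[j] = m
            out_cov[j] = (np.exp(lsa), np.exp(lsb), np.tanh(zr))
            out_nu[j] = nu

    return out_a, out_b, out_m, out_cov, out_nu


def _decentre(out_a, out_b, out_m, out_cov, k):
    """Map centred-time draws back to chi = alpha + beta * (T + t).

    With internal predictor a + b * (t - c) and k = T + c:
    alpha = a - k * b (per patient and for the population mean);
    the population covariance transforms as A Sigma A' with A = [[1, -k], [0, 1]].
    """
    alpha = out_a - k * out_b
    m_alpha = out_m[:, 0] - k * out_m[:, 1]
    va = out_cov[:, 0] ** 2
    vb = out_cov[:, 1] ** 2
    cab = out_cov[:, 2] * out_cov[:, 0] * out_cov[:, 1]
    va_new = va + k * k * vb - 2.0 * k * cab
    cab_new = cab - k * vb
    sd_a = np.sqrt(va_new)
    sd_b = out_cov[:, 1]
    rho = np.clip(cab_new / (sd_a * sd_b), -1.0, 1.0)
    return alpha, m_alpha, sd_a, sd_b, rho


def run_sampler(
    dataset: LongitudinalDataset,
    priors: PriorSpec,
    n_chains: int,
    n_warmup: int,
    n_draws: int,
    seed: int,
    rhat_limit: float,
    min_ess: float,
) -> PosteriorDraws:
    import arviz as az

    y, t, idx = dataset.arrays()
    order = np.argsort(idx, kind="stable")
    y, t, idx = y[order], t[order], idx[order]
    n_pat = dataset.n_patients
    counts = np.bincount(idx, minlength=n_pat)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    c = float(t.mean())
    tc = t - c
    k = dataset.centering_constant + c

    chains = []
    for ss in np.random.SeedSequence(seed).spawn(n_chains):
        rng = np.random.default_rng(ss)
        chains.append(
            _run_chain(y, tc, idx, starts, counts, n_pat, priors, n_warmup, n_draws, rng)
        )

    def stack(i):
        return np.stack([ch[i] for ch in chains])

    out_a, out_b, out_m, out_cov, out_nu = (stack(i) for i in range(5))
    alpha, m_alpha, sd_a, sd_b, rho = _decentre(
        out_a.reshape(-1, n_pat),
        out_b.reshape(-1, n_pat),
        out_m.reshape(-1, 2),
        out_cov.reshape(-1, 3),
        k,
    )
    shape = (n_chains, n_draws)
    post = {
        "pop_intercept": m_alpha.reshape(shape),
        "pop_slope": out_m[:, :, 1],
        "re_sd_intercept": sd_a.reshape(shape),
        "re_sd_slope": sd_b.reshape(shape),
        "re_correlation": rho.reshape(shape),
        "precision_nu": out_nu,
        "alpha": alpha.reshape(*shape, n_pat),
        "beta": out_b,
    }

    idata = az.from_dict(posterior=post)
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    pop_names = [
        "pop_intercept",
        "pop_slope",
        "re_sd_intercept",
        "re_sd_slope",
        "re_correlation",
        "precision_nu",
    ]
    diag = pd.DataFrame(
        {
            "rhat": {nm: float(rhat_ds[nm].values) for nm in pop_names},
            "ess": {nm: float(ess_ds[nm].values) for nm in pop_names},
        }
    )
    all_rhat = np.concatenate(
        [np.atleast_1d(rhat_ds[v].values).ravel() for v in rhat_ds.data_vars]
    )
    max_rhat = float(np.nanmax(all_rhat)) if np.any(np.isfinite(all_rhat)) else 1.0
    min_ess_pop = float(np.nanmin(diag["ess"].values))

    warn_msgs = []
    if max_rhat > rhat_limit:
        warn_msgs.append(
            f"non-convergence: max split-Rhat {max_rhat:.3f} exceeds limit {rhat_limit}"
        )
    if min_ess_pop < min_ess:
        warn_msgs.append(
            f"low effective sample size: min population ESS {min_ess_pop:.0f} < {min_ess}"
        )
    converged = not warn_msgs
    if warn_msgs:
        import warnings as _w

        for msg in warn_msgs:
            _w.warn(msg, RuntimeWarning, stacklevel=3)

    return PosteriorDraws(
        pop_intercept=post["pop_intercept"],
        pop_slope=post["pop_slope"],
        re_sd_intercept=post["re_sd_intercept"],
        re_sd_slope=post["re_sd_slope"],
        re_correlation=post["re_correlation"],
        precision_nu=post["precision_nu"],
        alpha=post["alpha"],
        beta=post["beta"],
        patient_ids=dataset.patient_ids,
        centering_constant=dataset.centering_constant,
        endpoint=dataset.endpoint,
        seed=seed,
        priors=priors,
        diagnostics=diag,
        converged=converged,
        warnings_=warn_msgs,
    )
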
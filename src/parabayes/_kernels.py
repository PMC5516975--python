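"""Jitted Gibbs / Metropolis-Hastings kernels for the whole-genome regression samplers.

The model throughout is

    y_i = mu + sum_j Z_ij * alpha_j + e_i,   e_i ~ N(0, sigma2_e)

with Z the raw 0/1/2 dosage codes.  The residual vector ``e = y - mu - Z a``
is carried incrementally: every update that changes ``mu`` or an ``alpha_j``
patches ``e`` in place, so one sweep over M loci costs O(n*M).

All randomness flows through a ``numpy.random.Generator`` passed in from the
caller, so a chain is fully reproducible from its seed and the same code
path runs jitted or (for unit testing) uncompiled.

Genotype columns are passed as a C-contiguous (M, n) float32 array ``Zt``
(one cache-friendly row per locus) with precomputed float64 ``zsq[j] =
z_j'z_j``; dot products accumulate in float64.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_NONFINITE = 1


@njit(cache=True, fastmath=True)
def _dot_f32(z, e):
    s = 0.0
    for i in range(z.shape[0]):
        s += z[i] * e[i]
    return s


@njit(cache=True, fastmath=True)
def _axpy_f32(z, e, c):
    # e += c * z
    for i in range(z.shape[0]):
        e[i] += c * z[i]


@njit(cache=True)
def sample_scaled_inv_chi2(rng, df, ssq):
    """One draw of sigma2 = ssq / chi2_df, i.e. scaled-inv-chi2(df, ssq/df)."""
    return ssq / (2.0 * rng.standard_gamma(0.5 * df))


@njit(cache=True)
def update_mu(rng, e, mu, sigma2_e):
    """Gibbs draw of the overall mean; patches the residual vector. Returns new mu."""
    n = e.shape[0]
    m = 0.0
    for i in range(n):
        m += e[i]
    m = m / n + mu  # mean of (y - Z a)
    mu_new = rng.normal(m, np.sqrt(sigma2_e / n))
    d = mu_new - mu
    for i in range(n):
        e[i] -= d
    return mu_new


@njit(cache=True)
def update_effect_normal(rng, z, zsq, e, alpha_j, s2a, s2e):
    """Gibbs draw of one marker effect from its normal full conditional.

    Conditional: alpha_j ~ N(chat, C) with
        C    = s2e / (z'z + s2e/s2a)
        chat = z'(e + z*alpha_old) / (z'z + s2e/s2a).
    A locus with z'z = 0 falls back to its prior N(0, s2a).  Returns the new
    alpha_j; the residual vector is patched in place.
    """
    r = _dot_f32(z, e) + zsq * alpha_j
    denom = zsq + s2e / s2a
    chat = r / denom
    C = s2e / denom
    a_new = chat + np.sqrt(C) * rng.standard_normal()
    if a_new != alpha_j:
        _axpy_f32(z, e, alpha_j - a_new)
    return a_new


@njit(cache=True)
def sample_effect_variance(rng, alpha_j, nu, S):
    """Locus-variance draw: sigma2_aj = (nu*S + alpha_j^2) / chi2_{nu+1}."""
    return sample_scaled_inv_chi2(rng, nu + 1.0, nu * S + alpha_j * alpha_j)


@njit(cache=True)
def _marginal_loglik(r, zsq, s2, s2e):
    # log N(r; 0, (z'z)^2 s2 + z'z s2e), dropping constants
    v = zsq * zsq * s2 + zsq * s2e
    return -0.5 * (np.log(v) + r * r / v)


@njit(cache=True)
def update_locus_bayesB(rng, z, zsq, e, alpha_j, s2a_j, s2e, nu, S, pi, n_mh):
    """Metropolis-Hastings update of one locus variance, then its effect.

    Candidates come from the prior mixture (0 with probability pi, else
    nu*S/chi2_nu); the acceptance ratio uses the likelihood of
    r_j = z_j'(e + z_j alpha_j) with alpha_j integrated out.  After n_mh
    cycles the effect is drawn from its normal conditional when the variance
    is positive, else set to zero.  Returns (alpha_j, s2a_j).
    """
    r = _dot_f32(z, e) + zsq * alpha_j
    s2_cur = s2a_j
    if zsq <= 0.0:
        # no data at this locus: MH chain samples the prior directly
        if rng.random() < pi:
            s2_cur = 0.0
        else:
            s2_cur = sample_scaled_inv_chi2(rng, nu, nu * S)
    else:
        ll_cur = _marginal_loglik(r, zsq, s2_cur, s2e)
        for _ in range(n_mh):
            if rng.random() < pi:
                s2_cand = 0.0
            else:
                s2_cand = sample_scaled_inv_chi2(rng, nu, nu * S)
            ll_cand = _marginal_loglik(r, zsq, s2_cand, s2e)
            if ll_cand >= ll_cur or np.log(rng.random()) < ll_cand - ll_cur:
                s2_cur = s2_cand
                ll_cur = ll_cand
    if s2_cur > 0.0:
        a_new = update_effect_normal(rng, z, zsq, e, alpha_j, s2_cur, s2e)
    else:
        a_new = 0.0
        if alpha_j != 0.0:
            _axpy_f32(z, e, alpha_j)
    return a_new, s2_cur


@njit(cache=True)
def update_locus_bayesCpi(rng, z, zsq, e, alpha_j, s2a, s2e, pi):
    """Sample the inclusion indicator and effect of one locus (common variance).

    delta_j's full conditional compares the marginal likelihood of
    r_j under inclusion (variance (z'z)^2 s2a + z'z s2e) against exclusion
    (variance z'z s2e), with prior odds (1-pi)/pi.  Returns (alpha_j, delta_j).
    """
    r = _dot_f32(z, e) + zsq * alpha_j
    if zsq <= 0.0:
        p1 = 1.0 - pi
    else:
        v0 = zsq * s2e
        v1 = zsq * zsq * s2a + v0
        log_bf = -0.5 * (np.log(v1) - np.log(v0)) - 0.5 * r * r * (1.0 / v1 - 1.0 / v0)
        log_odds = np.log((1.0 - pi) / pi) + log_bf
        if log_odds > 35.0:
            p1 = 1.0
        elif log_odds < -35.0:
            p1 = 0.0
        else:
            p1 = 1.0 / (1.0 + np.exp(-log_odds))
    if rng.random() < p1:
        a_new = update_effect_normal(rng, z, zsq, e, alpha_j, s2a, s2e)
        return a_new, 1
    if alpha_j != 0.0:
        _axpy_f32(z, e, alpha_j)
    return 0.0, 0


@njit(cache=True)
def update_residual_variance(rng, e, res_nu, res_scale):
    """sigma2_e ~ scaled-inv-chi2 with df n+res_nu and sum of squares e'e + res_nu*res_scale."""
    n = e.shape[0]
    sse = 0.0
    for i in range(n):
        sse += e[i] * e[i]
    return sample_scaled_inv_chi2(rng, n + res_nu, sse + res_nu * res_scale)


@njit(cache=True)
def _sample_beta(rng, a, b):
    x = rng.standard_gamma(a)
    y = rng.standard_gamma(b)
    return x / (x + y)


@njit(cache=True)
def run_chain_kernel(
    rng,
    Zt,  # (M, n) float32, C-contiguous
    zsq,  # (M,) float64
    y,  # (n,) float64
    method,  # 0 = bayesA, 1 = bayesB, 2 = bayesCpi
    nu,
    S,
    pi_init,
    res_nu,
    res_scale,
    n_mh,
    total_iter,
    burn_in,
    s2e_init,
    thin_trace,
):
    """Run one MCMC chain; returns posterior summaries, traces and final state.

    Post-burn-in draws of the marker effects are accumulated into their
    running mean g_j; the residual-variance and (BayesCpi) pi traces keep one
    value per kept iteration.  Returns
    (status, bad_iter, g_mean, mu_mean, s2e_trace, pi_trace,
     alpha, s2a, delta, mu, s2e, pi, e, incl_freq).
    """
    M, n = Zt.shape
    alpha = np.zeros(M)
    s2a = np.full(M, S)
    delta = np.ones(M, dtype=np.int8)
    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    e = y.copy()
    for i in range(n):
        e[i] -= mu
    s2e = s2e_init
    pi = pi_init
    s2a_common = S

    kept = total_iter - burn_in
    g_sum = np.zeros(M)
    incl_sum = np.zeros(M)
    mu_sum = 0.0
    n_trace = (total_iter + thin_trace - 1) // thin_trace
    s2e_trace = np.empty(n_trace)
    pi_trace = np.empty(n_trace if method == 2 else 0)
    t_idx = 0

    for it in range(total_iter):
        mu = update_mu(rng, e, mu, s2e)
        if method == 0:  # BayesA
            for j in range(M):
                alpha[j] = update_effect_normal(rng, Zt[j], zsq[j], e, alpha[j], s2a[j], s2e)
                s2a[j] = sample_effect_variance(rng, alpha[j], nu, S)
        elif method == 1:  # BayesB
            for j in range(M):
                alpha[j], s2a[j] = update_locus_bayesB(
                    rng, Zt[j], zsq[j], e, alpha[j], s2a[j], s2e, nu, S, pi, n_mh
                )
                delta[j] = 1 if s2a[j] > 0.0 else 0
        else:  # BayesCpi
            m1 = 0
            ssq = nu * S
            for j in range(M):
                alpha[j], d_j = update_locus_bayesCpi(
                    rng, Zt[j], zsq[j], e, alpha[j], s2a_common, s2e, pi
                )
                delta[j] = d_j
                if d_j == 1:
                    m1 += 1
                    ssq += alpha[j] * alpha[j]
            s2a_common = sample_scaled_inv_chi2(rng, nu + m1, ssq)
            pi = _sample_beta(rng, M - m1 + 1.0, m1 + 1.0)
        s2e = update_residual_variance(rng, e, res_nu, res_scale)
        if not np.isfinite(s2e):
            return (
                STATUS_NONFINITE, it, g_sum, mu_sum, s2e_trace[:t_idx],
                pi_trace[:t_idx] if method == 2 else pi_trace,
                alpha, s2a, delta, mu, s2e, pi, e, incl_sum,
            )
        if it % thin_trace == 0:
            s2e_trace[t_idx] = s2e
            if method == 2:
                pi_trace[t_idx] = pi
            t_idx += 1
        if it >= burn_in:
            for j in range(M):
                g_sum[j] += alpha[j]
                incl_sum[j] += delta[j]
            mu_sum += mu

    g_mean = g_sum / kept
    incl_freq = incl_sum / kept
    return (
        STATUS_OK, -1, g_mean, mu_sum / kept, s2e_trace[:t_idx],
        pi_trace[:t_idx] if method == 2 else pi_trace,
        alpha, s2a, delta, mu, s2e, pi, e, incl_freq,
    )
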
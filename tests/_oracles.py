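"""Independent oracles used by the tests.

Everything here is deliberately implemented by a different route than the
package: brute-force enumeration for the Hardy-Weinberg exact test, dense
2-D quadrature for single-marker posteriors, a single-locus Wright-Fisher
frequency simulation, and ridge-regression SNP-BLUP for the GBLUP
equivalence check.
"""

from math import lgamma

import numpy as np
from scipy.special import gammaln


def hwe_exact_brute(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p-value by direct enumeration of heterozygote counts."""
    n = n_AA + n_Aa + n_aa
    nr = 2 * min(n_AA, n_aa) + n_Aa
    if nr == 0:
        return 1.0
    hets = range(nr % 2, min(nr, 2 * n - nr) + 1, 2)

    def logprob(h: int) -> float:
        homr = (nr - h) // 2
        homc = n - h - homr
        lg = lambda x: lgamma(x + 1)
        return (
            lg(n) - lg(h) - lg(homr) - lg(homc)
            + h * np.log(2.0) + lg(nr) + lg(2 * n - nr) - lg(2 * n)
        )

    ps = {h: np.exp(logprob(h)) for h in hets}
    tot = sum(ps.values())
    p_obs = ps[n_Aa] / tot
    return min(1.0, sum(p for p in ps.values() if p / tot <= p_obs * (1 + 1e-12)) / tot)


def _marg_and_blup(y, z, s2a, s2e):
    """Log marginal likelihood of y (mu integrated flat) and E[alpha | variances]."""
    n = len(y)
    V = np.outer(z, z) * s2a + s2e * np.eye(n)
    Vi = np.linalg.inv(V)
    one = np.ones(n)
    denom = one @ Vi @ one
    mu = (one @ Vi @ y) / denom
    r = y - mu * one
    _, logdet = np.linalg.slogdet(V)
    ll = -0.5 * (logdet + np.log(denom) + r @ Vi @ r)
    return ll, s2a * (z @ Vi @ r)


def _sichi2_logpdf(x, nu, S):
    return (
        (0.5 * nu) * np.log(0.5 * nu * S)
        - gammaln(0.5 * nu)
        - (0.5 * nu + 1) * np.log(x)
        - 0.5 * nu * S / x
    )


def single_marker_posterior_mean(y, z, nu, S, slab_weight, npts=160):
    """Posterior mean of the marker effect by 2-D log-grid quadrature.

    Model: y = 1 mu + z alpha + e, flat priors on mu and sigma2_e,
    alpha ~ N(0, s2a), s2a ~ scaled-inv-chi2(nu, S); with prior probability
    ``1 - slab_weight`` the effect is a point mass at zero.
    """
    s2e_grid = np.exp(np.linspace(np.log(1e-5), np.log(20.0), npts))
    s2a_grid = np.exp(np.linspace(np.log(1e-6), np.log(400.0), npts))
    lw = np.empty((npts, npts))
    ah = np.empty((npts, npts))
    for i, sa in enumerate(s2a_grid):
        lpa = _sichi2_logpdf(sa, nu, S)
        for j, se in enumerate(s2e_grid):
            ll, a = _marg_and_blup(y, z, sa, se)
            lw[i, j] = ll + lpa + np.log(sa) + np.log(se)  # log-grid jacobians
            ah[i, j] = a
    m = lw.max()
    w = np.exp(lw - m)
    dls = np.log(s2a_grid[1] / s2a_grid[0])
    dle = np.log(s2e_grid[1] / s2e_grid[0])
    den_slab = w.sum() * dls * dle
    num = (w * ah).sum() * dls * dle
    lw0 = np.array([_marg_and_blup(y, z, 0.0, se)[0] + np.log(se) for se in s2e_grid])
    den_spike = np.exp(lw0 - m).sum() * dle
    w1 = slab_weight
    return w1 * num / (w1 * den_slab + (1.0 - w1) * den_spike)


def wf_single_locus_frequencies(
    n_loci: int, pop_size: int, mutation_rate: float, generations: int, seed: int
) -> np.ndarray:
    """Final allele frequencies of independent single-locus Wright-Fisher runs.

    Each locus starts at frequency 0.5 in a diploid population of
    ``pop_size`` and evolves by binomial resampling of 2N gametes with
    symmetric allele-flip mutation.
    """
    rng = np.random.default_rng(seed)
    two_n = 2 * pop_size
    p = np.full(n_loci, 0.5)
    for _ in range(generations):
        p_mut = p * (1 - mutation_rate) + (1 - p) * mutation_rate
        p = rng.binomial(two_n, p_mut) / two_n
    return p


def snp_blup_gebv(Z, y_train, train_idx, s2g, s2e):
    """Ridge-regression (SNP-BLUP) GEBVs, the mixed-model dual of GBLUP.

    Per-marker variance is s2g / (2 sum q(1-q)); solves the primal normal
    equations (M x M), a different computational route than the n x n
    mixed-model solve.
    """
    q = Z.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(q * (1 - q))
    Zc = Z - 2.0 * q[None, :]
    s2a = s2g / denom
    lam = s2e / s2a
    Zt = Zc[train_idx]
    # GLS intercept under the equivalent marker model
    V = s2a * (Zt @ Zt.T) + s2e * np.eye(len(train_idx))
    Vi = np.linalg.inv(V)
    one = np.ones(len(train_idx))
    mu = (one @ Vi @ y_train) / (one @ Vi @ one)
    alpha = np.linalg.solve(Zt.T @ Zt + lam * np.eye(Z.shape[1]), Zt.T @ (y_train - mu))
    return Zc @ alpha
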
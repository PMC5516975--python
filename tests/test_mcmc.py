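"""Sampler correctness: full-conditional moments, chain bookkeeping, method relations."""

import numpy as np
import pytest
from scipy import stats

import parabayes as pb
from parabayes import _kernels


def test_priorspec_defaults_and_validation():
    a = pb.PriorSpec.for_method("bayesA")
    assert (a.nu, a.scale, a.pi_zero) == (4.012, 0.0020, 0.0)
    b = pb.PriorSpec.for_method("bayesB")
    assert (b.nu, b.scale, b.pi_zero) == (4.234, 0.0429, 0.99)
    c = pb.PriorSpec.for_method("bayesCpi")
    assert c.nu == 4.2 and c.scale is None
    with pytest.raises(ValueError):
        pb.PriorSpec.for_method("bayesB", pi_zero=1.0)
    with pytest.raises(ValueError):
        pb.PriorSpec.for_method("bayesA", nu=-1.0)
    with pytest.raises(ValueError):
        pb.PriorSpec.for_method("bayesRidge")


def test_bayescpi_scale_derivation():
    prior = pb.PriorSpec.for_method("bayesCpi")
    y = np.array([1.0, 2.0, 3.0, 4.0])
    q = np.array([0.5, 0.25])
    het = 2 * (0.25 + 0.1875)
    expected = 0.5 * np.var(y) / ((1 - 0.99) * het) * (4.2 - 2) / 4.2
    assert prior.derive_scale(y, q) == pytest.approx(expected)
    with pytest.raises(ValueError, match="monomorphic"):
        prior.derive_scale(y, np.array([0.0, 1.0]))


# --- conjugate full-conditional moments ----------------------------------


def test_update_mu_moments(rng):
    n = 50
    e0 = rng.standard_normal(n) + 0.8
    mu0, s2e = 1.2, 2.0
    target_mean = e0.mean() + mu0
    draws = np.array(
        [_kernels.update_mu(rng, e0.copy(), mu0, s2e) for _ in range(200_000)]
    )
    assert draws.mean() == pytest.approx(target_mean, rel=0.01)
    assert draws.var() == pytest.approx(s2e / n, rel=0.01)


def test_update_mu_patches_residuals(rng):
    e = np.array([1.0, 2.0, 3.0])
    mu_new = _kernels.update_mu(rng, e, 0.5, 1.0)
    np.testing.assert_allclose(e, np.array([1.0, 2.0, 3.0]) - (mu_new - 0.5))


def test_effect_normal_moments_match_closed_form(rng):
    """Toy n=4 system: empirical mean/variance vs the analytic conditional."""
    z = np.array([1.0, 2.0, 0.0, 1.0], dtype=np.float32)
    zsq = float((z.astype(float) ** 2).sum())
    e0 = np.array([0.9, 2.1, -0.3, 1.2])
    alpha_old, s2a, s2e = 0.4, 0.7, 1.3
    r = float(z.astype(float) @ e0) + zsq * alpha_old
    denom = zsq + s2e / s2a
    chat, C = r / denom, s2e / denom
    draws = np.array(
        [
            _kernels.update_effect_normal(rng, z, zsq, e0.copy(), alpha_old, s2a, s2e)
            for _ in range(200_000)
        ]
    )
    assert draws.mean() == pytest.approx(chat, rel=0.01)
    assert draws.var() == pytest.approx(C, rel=0.01)


def test_effect_normal_ridge_limits(rng):
    z = np.array([1.0, 2.0, 0.0, 1.0], dtype=np.float32)
    zsq = float((z.astype(float) ** 2).sum())
    e0 = np.array([0.9, 2.1, -0.3, 1.2])
    r = float(z.astype(float) @ e0)
    ls = r / zsq  # least-squares estimate of the effect (alpha_old = 0)
    big = np.mean(
        [_kernels.update_effect_normal(rng, z, zsq, e0.copy(), 0.0, 1e9, 1.0)
         for _ in range(20_000)]
    )
    assert big == pytest.approx(ls, rel=0.02)
    small = np.mean(
        [_kernels.update_effect_normal(rng, z, zsq, e0.copy(), 0.0, 1e-12, 1.0)
         for _ in range(200)]
    )
    assert abs(small) < 1e-5


def test_effect_normal_zero_marker_draws_from_prior(rng):
    z = np.zeros(4, dtype=np.float32)
    draws = np.array(
        [_kernels.update_effect_normal(rng, z, 0.0, np.ones(4), 0.0, 0.5, 2.0)
         for _ in range(100_000)]
    )
    assert draws.mean() == pytest.approx(0.0, abs=0.01)
    assert draws.var() == pytest.approx(0.5, rel=0.02)


def test_shrinkage_monotone_in_residual_variance(rng):
    z = np.array([1.0, 2.0, 0.0, 1.0], dtype=np.float32)
    zsq = float((z.astype(float) ** 2).sum())
    e0 = np.array([0.9, 2.1, -0.3, 1.2])
    means = [
        np.mean([_kernels.update_effect_normal(rng, z, zsq, e0.copy(), 0.0, 0.7, s2e)
                 for _ in range(30_000)])
        for s2e in (0.5, 5.0, 50.0)
    ]
    assert abs(means[0]) > abs(means[1]) > abs(means[2])


def test_effect_variance_mean_and_positivity(rng):
    nu, S = 4.012, 0.0020
    draws = np.array(
        [_kernels.sample_effect_variance(rng, 0.0, nu, S) for _ in range(1_000_000)]
    )
    assert (draws > 0).all()
    # E[(nu S + a^2)/chi2_{nu+1}] = nu S / (nu - 1)
    assert draws.mean() == pytest.approx(nu * S / (nu - 1), rel=0.01)


def test_effect_variance_with_alpha_mean(rng):
    nu, S, a = 4.2, 0.05, 0.3
    draws = np.array(
        [_kernels.sample_effect_variance(rng, a, nu, S) for _ in range(400_000)]
    )
    assert draws.mean() == pytest.approx((nu * S + a * a) / (nu - 1), rel=0.01)


def test_effect_variance_stochastically_increasing_in_alpha(rng):
    small = np.sort([_kernels.sample_effect_variance(rng, 0.0, 4.234, 0.0429)
                     for _ in range(100_000)])
    large = np.sort([_kernels.sample_effect_variance(rng, 1.0, 4.234, 0.0429)
                     for _ in range(100_000)])
    qs = np.linspace(0.02, 0.98, 25)
    assert (np.quantile(large, qs) > np.quantile(small, qs)).all()


def test_residual_variance_mean(rng):
    n = 100
    e = np.full(n, 1.0)  # e'e = 100
    draws = np.array(
        [_kernels.update_residual_variance(rng, e, -2.0, 0.0) for _ in range(200_000)]
    )
    # ssq/chi2_{n-2} has mean ssq/(n-4)
    assert draws.mean() == pytest.approx(100.0 / 96.0, rel=0.01)
    assert (draws > 0).all()


def test_residual_variance_scale_property(rng):
    n = 60
    e = np.random.default_rng(7).standard_normal(n)
    d1 = np.array([_kernels.update_residual_variance(rng, e, -2.0, 0.0)
                   for _ in range(50_000)])
    d2 = np.array([_kernels.update_residual_variance(rng, np.sqrt(2.0) * e, -2.0, 0.0)
                   for _ in range(50_000)])
    ks = stats.ks_2samp(2.0 * d1, d2)
    assert ks.pvalue > 0.01


def test_beta_draw_moments(rng):
    M = 500  # all indicators zero: pi ~ Beta(M+1, 1)
    draws = np.array([_kernels._sample_beta(rng, M + 1.0, 1.0) for _ in range(200_000)])
    assert draws.mean() == pytest.approx((M + 1) / (M + 2), rel=0.001)


def test_cpi_indicator_conditional_matches_quadrature(rng):
    """Inclusion probability of one locus vs numerical integration over the effect."""
    z = np.array([0.0, 1.0, 2.0, 1.0, 0.0], dtype=np.float32)
    zsq = float((z.astype(float) ** 2).sum())
    e0 = np.array([0.1, 0.45, 0.9, 0.5, -0.05])
    s2a, s2e, pi = 0.05, 0.3, 0.99
    r = float(z.astype(float) @ e0)
    # oracle: r | delta=1 ~ int N(r; zsq*a, zsq*s2e) N(a; 0, s2a) da, by quadrature
    a_grid = np.linspace(-3, 3, 20_001)
    da = a_grid[1] - a_grid[0]
    like1 = np.sum(
        stats.norm.pdf(r, zsq * a_grid, np.sqrt(zsq * s2e))
        * stats.norm.pdf(a_grid, 0, np.sqrt(s2a))
    ) * da
    like0 = stats.norm.pdf(r, 0, np.sqrt(zsq * s2e))
    p1 = (1 - pi) * like1 / ((1 - pi) * like1 + pi * like0)
    n_rep = 200_000
    incl = 0
    for _ in range(n_rep):
        _, d = _kernels.update_locus_bayesCpi(rng, z, zsq, e0.copy(), 0.0, s2a, s2e, pi)
        incl += d
    freq = incl / n_rep
    se = np.sqrt(p1 * (1 - p1) / n_rep)
    assert abs(freq - p1) < 4 * se + 1e-4, (freq, p1)


def test_bayesb_prior_predictive_inclusion(rng):
    """With null data the BayesB indicator frequency stays at its prior 1-pi."""
    z = np.full(5, 0.1, dtype=np.float32)
    zsq = float((z.astype(float) ** 2).sum())  # small: likelihood ~ flat
    pi, nu, S, s2e = 0.99, 4.234, 0.0429, 10.0
    n_rep = 200_000
    incl = 0
    for _ in range(n_rep):
        _, s2 = _kernels.update_locus_bayesB(
            rng, z, zsq, np.zeros(5), 0.0, 0.0, s2e, nu, S, pi, 1
        )
        incl += s2 > 0
    freq = incl / n_rep
    se = np.sqrt(0.01 * 0.99 / n_rep)
    assert abs(freq - 0.01) < 3 * se


# --- chain-level behavior -------------------------------------------------


def test_chain_bookkeeping(small_sim):
    cs = pb.run_chain("bayesA", small_sim.genotypes, small_sim.phenotypes,
                      total_iter=500, burn_in=100, seed=1)
    assert cs.kept_iterations == 400
    assert cs.full_residual_trace.shape == (500,)
    assert cs.residual_variance_trace.shape == (400,)
    assert np.isfinite(cs.posterior_mean_effects).all()


def test_chain_rejects_constant_phenotype(small_sim):
    with pytest.raises(ValueError, match="zero variance"):
        pb.run_chain("bayesA", small_sim.genotypes,
                     np.ones(small_sim.genotypes.n_individuals),
                     total_iter=100, burn_in=10)


def test_chain_seed_determinism(small_sim):
    kw = dict(total_iter=300, burn_in=50, seed=77)
    for method in pb.mcmc.METHODS:
        a = pb.run_chain(method, small_sim.genotypes, small_sim.phenotypes, **kw)
        b = pb.run_chain(method, small_sim.genotypes, small_sim.phenotypes, **kw)
        np.testing.assert_array_equal(a.posterior_mean_effects, b.posterior_mean_effects)
        np.testing.assert_array_equal(a.full_residual_trace, b.full_residual_trace)


@pytest.mark.parametrize("method", ["bayesA", "bayesB", "bayesCpi"])
def test_residual_vector_consistency(small_sim, method):
    """Incremental residual updates do not drift over 1000 iterations."""
    cs = pb.run_chain(method, small_sim.genotypes, small_sim.phenotypes,
                      total_iter=1000, burn_in=100, seed=3)
    st = cs.final_state
    e_direct = (
        small_sim.phenotypes - st["mu"] - small_sim.genotypes.dosages @ st["alpha"]
    )
    assert np.abs(e_direct - st["residuals"]).max() <= 1e-6


def test_zero_variance_marker_column_handled(small_sim):
    Z = small_sim.genotypes.dosages[:, :50].copy()
    Z[:, 7] = 0.0
    y = small_sim.phenotypes
    for method in pb.mcmc.METHODS:
        cs = pb.run_chain(method, Z, y, total_iter=200, burn_in=50, seed=2)
        assert np.isfinite(cs.posterior_mean_effects).all()


def test_bayesb_with_pi_zero_equals_bayesa(small_sim):
    """BayesB at pi=0 targets the BayesA posterior with matching (nu, S)."""
    y = small_sim.phenotypes
    G = small_sim.genotypes
    prior_b = pb.PriorSpec.for_method("bayesB", pi_zero=0.0)
    prior_a = pb.PriorSpec.for_method("bayesA", nu=4.234, scale=0.0429)
    gb = pb.run_chain("bayesB", G, y, prior=prior_b, total_iter=6000, burn_in=1000,
                      seed=11).posterior_mean_effects
    ga = pb.run_chain("bayesA", G, y, prior=prior_a, total_iter=6000, burn_in=1000,
                      seed=12).posterior_mean_effects
    assert np.corrcoef(ga, gb)[0, 1] > 0.99


def test_bayescpi_pi_high_on_null_data(rng):
    """With no QTL, the posterior of pi concentrates near 1 for M >= 500."""
    Z = rng.binomial(2, 0.3, size=(200, 500)).astype(float)
    y = rng.standard_normal(200)
    cs = pb.run_chain("bayesCpi", Z, y, total_iter=3000, burn_in=500, seed=4)
    assert cs.posterior_mean_pi > 0.9
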
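"""Single-chain BayesA / BayesB / BayesCpi whole-genome regression samplers.

The three methods share the linear model

    y_i = mu + sum_j Z_ij alpha_j + e_i

and differ only in the marker-effect prior:

* **BayesA** — every locus has an effect; alpha_j ~ N(0, sigma2_aj) with a
  locus-specific scaled-inverse-chi-square variance prior chi^-2(nu, S),
  nu = 4.012, S = 0.0020.
* **BayesB** — a locus has zero variance with probability pi (default 0.99),
  else sigma2_aj ~ chi^-2(nu, S) with nu = 4.234, S = 0.0429; the variance is
  sampled by Metropolis-Hastings with the effect integrated out.
* **BayesCpi** — a single common effect variance chi^-2(nu, S) with nu = 4.2
  replaces the locus-specific ones; the zero-effect probability pi carries a
  uniform(0,1) prior and is sampled.  S is derived from the data at startup
  (see :meth:`PriorSpec.derive_scale`) unless supplied.

The residual variance carries a flat prior by default (nu = -2, scale = 0),
so sigma2_e | e ~ e'e / chi2_{n-2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .genoio import GenotypeMatrix

__all__ = ["PriorSpec", "ChainSamples", "run_chain", "METHODS"]

METHODS = ("bayesA", "bayesB", "bayesCpi")
_METHOD_CODE = {"bayesA": 0, "bayesB": 1, "bayesCpi": 2}

# (nu, S, pi) defaults per method
_DEFAULTS = {
    "bayesA": (4.012, 0.0020, 0.0),
    "bayesB": (4.234, 0.0429, 0.99),
    "bayesCpi": (4.2, None, 0.5),  # S derived from data; pi initialized at its uniform-prior mean
}


@dataclass
class PriorSpec:
    """Hyperparameters of one whole-genome regression method.

    ``pi_zero`` is the prior probability of a zero effect: fixed for BayesB,
    the *initial* value of the sampled pi for BayesCpi.  ``scale=None`` for
    BayesCpi requests the data-derived scale.  ``n_mh`` is the number of
    Metropolis-Hastings cycles per locus per iteration in BayesB.
    """

    method: str
    nu: float
    scale: Optional[float]
    pi_zero: float
    residual_nu: float = -2.0
    residual_scale: float = 0.0
    n_mh: int = 10

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        if self.scale is not None and self.scale < 0:
            raise ValueError("scale must be non-negative")
        if not 0.0 <= self.pi_zero < 1.0:
            raise ValueError("pi_zero must lie in [0, 1)")
        if self.n_mh < 1:
            raise ValueError("n_mh must be >= 1")

    @classmethod
    def for_method(cls, method: str, **overrides) -> "PriorSpec":
        """The method's default priors (nu, S, pi), optionally overridden."""
        if method not in _DEFAULTS:
            raise ValueError(f"method must be one of {METHODS}, got {method!r}")
        nu, scale, pi = _DEFAULTS[method]
        kw = dict(method=method, nu=nu, scale=scale, pi_zero=pi)
        kw.update(overrides)
        return cls(**kw)

    def derive_scale(self, y: np.ndarray, q: np.ndarray, pi0: float = 0.99) -> float:
        """Data-derived scale S for BayesCpi.

        Assumes half the phenotypic variance is genetic and spreads it over
        the expected fraction (1 - pi0) of markers:

            S = sigma2_tilde * (nu - 2) / nu,
            sigma2_tilde = 0.5 * var(y) / ((1 - pi0) * sum_j 2 q_j (1 - q_j)).
        """
        het = float(np.sum(2.0 * q * (1.0 - q)))
        if het <= 0:
            raise ValueError("all markers monomorphic; cannot derive a scale")
        s2 = 0.5 * float(np.var(y)) / ((1.0 - pi0) * het)
        return s2 * (self.nu - 2.0) / self.nu


@dataclass
class ChainSamples:
    """Posterior summaries and traces from one chain."""

    method: str
    posterior_mean_effects: np.ndarray  # g_j, averaged over kept iterations
    posterior_mean_mu: float
    full_residual_trace: np.ndarray  # sigma2_e, one value per iteration (incl. burn-in)
    burn_in: int
    kept_iterations: int
    seed: int
    pi_trace_full: Optional[np.ndarray] = None  # BayesCpi only
    inclusion_frequency: Optional[np.ndarray] = None
    final_state: dict = field(default_factory=dict)

    @property
    def residual_variance_trace(self) -> np.ndarray:
        """Post-burn-in residual-variance draws."""
        return self.full_residual_trace[self.burn_in:]

    @property
    def pi_trace(self) -> Optional[np.ndarray]:
        if self.pi_trace_full is None:
            return None
        return self.pi_trace_full[self.burn_in:]

    @property
    def posterior_mean_pi(self) -> Optional[float]:
        tr = self.pi_trace
        return None if tr is None or tr.size == 0 else float(tr.mean())


def _as_dosage_array(genotypes) -> np.ndarray:
    if isinstance(genotypes, GenotypeMatrix):
        Z = genotypes.dosages
    else:
        Z = np.asarray(genotypes, dtype=float)
    if Z.ndim != 2:
        raise ValueError("genotypes must be a 2-D individuals x markers array")
    if np.isnan(Z).any():
        raise ValueError("genotypes contain missing values; impute first")
    return Z


def run_chain(
    method: str,
    genotypes,
    y: np.ndarray,
    prior: PriorSpec | None = None,
    total_iter: int = 50_000,
    burn_in: int = 5_000,
    seed: int = 0,
    s2e_init: float | None = None,
) -> ChainSamples:
    """Run one MCMC chain of the requested method and summarize it.

    Each iteration sweeps the full conditional schedule (mu, every locus,
    variances, and pi for BayesCpi).  Post-burn-in effect draws are averaged
    into the posterior-mean effects g_j.  Fully reproducible given ``seed``.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if not 0 <= burn_in < total_iter:
        raise ValueError("need 0 <= burn_in < total_iter")
    Z = _as_dosage_array(genotypes)
    y = np.asarray(y, dtype=float)
    n, M = Z.shape
    if y.shape != (n,):
        raise ValueError(f"y has shape {y.shape}, expected ({n},)")
    vy = float(np.var(y))
    if vy == 0.0:
        raise ValueError("phenotype has zero variance")
    if prior is None:
        prior = PriorSpec.for_method(method)
    if prior.method != method:
        raise ValueError(f"prior is for {prior.method!r}, chain is {method!r}")
    if n + prior.residual_nu <= 0:
        raise ValueError(
            f"residual-variance draw needs n + residual_nu > 0 (n={n}, nu={prior.residual_nu})"
        )
    scale = prior.scale
    if scale is None:
        q = Z.mean(axis=0) / 2.0
        scale = prior.derive_scale(y, q)

    Zt = np.ascontiguousarray(Z.T, dtype=np.float32)
    zsq = (Z.astype(np.float64) ** 2).sum(axis=0)
    rng = np.random.default_rng(seed)
    out = _kernels.run_chain_kernel(
        rng,
        Zt,
        zsq,
        y,
        _METHOD_CODE[method],
        float(prior.nu),
        float(scale),
        float(prior.pi_zero),
        float(prior.residual_nu),
        float(prior.residual_scale),
        int(prior.n_mh),
        int(total_iter),
        int(burn_in),
        float(s2e_init) if s2e_init is not None else 0.5 * vy,
        1,
    )
    (status, bad_iter, g_mean, mu_mean, s2e_trace, pi_trace,
     alpha, s2a, delta, mu, s2e, pi, e, incl_freq) = out
    if status != _kernels.STATUS_OK:
        raise FloatingPointError(
            f"non-finite sampler state at iteration {bad_iter} ({method})"
        )
    return ChainSamples(
        method=method,
        posterior_mean_effects=np.asarray(g_mean),
        posterior_mean_mu=float(mu_mean),
        full_residual_trace=np.asarray(s2e_trace),
        burn_in=burn_in,
        kept_iterations=total_iter - burn_in,
        seed=seed,
        pi_trace_full=np.asarray(pi_trace) if method == "bayesCpi" else None,
        inclusion_frequency=np.asarray(incl_freq),
        final_state={
            "mu": float(mu),
            "alpha": np.asarray(alpha),
            "effect_variances": np.asarray(s2a),
            "delta": np.asarray(delta),
            "sigma2_e": float(s2e),
            "pi": float(pi),
            "residuals": np.asarray(e),
            "scale_used": float(scale),
        },
    )
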
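"""GBLUP: VanRaden genomic relationship matrix, REML variance components, prediction.

The genomic relationship matrix is VanRaden's first formulation,

    G = Z Z' / (2 * sum_i q_i (1 - q_i)),

with Z the dosage matrix column-centered at twice the observed counted-allele
frequency q_i.  Heritability is estimated by restricted maximum likelihood
under the animal model y = 1 mu + g + e, g ~ N(0, G sigma2_g),
e ~ N(0, I sigma2_e): a single eigendecomposition of G reduces the restricted
likelihood to a cheap one-dimensional profile in h2 = sigma2_g / (sigma2_g +
sigma2_e), maximized on [0, 1].  GEBVs for individuals with masked phenotypes
come from the conditional-mean (mixed-model) equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize_scalar

from .genoio import GenotypeMatrix

__all__ = ["GMatrix", "VarianceComponents", "vanraden_G", "reml_h2", "gblup_predict"]

_JITTER = 1e-8


@dataclass
class GMatrix:
    """VanRaden genomic relationship matrix with its centering frequencies."""

    matrix: np.ndarray  # n x n
    centering_frequencies: np.ndarray  # q_i per marker
    denominator: float  # 2 * sum q_i (1 - q_i)
    individual_ids: list[str] | None = None


@dataclass
class VarianceComponents:
    """REML estimates under the animal model."""

    genetic_variance: float
    residual_variance: float
    heritability: float
    log_likelihood: float
    boundary: bool = False  # optimum at the h2 boundary or flat likelihood


def _dosages(genotypes) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(genotypes, GenotypeMatrix):
        Z = genotypes.dosages
        ids = list(genotypes.individual_ids)
    else:
        Z = np.asarray(genotypes, dtype=float)
        ids = None
    if np.isnan(Z).any():
        raise ValueError("genotypes contain missing values; impute first")
    return Z, ids


def vanraden_G(genotypes, frequencies: np.ndarray | None = None) -> GMatrix:
    """Build G = ZZ' / (2 sum q(1-q)) from 0/1/2 dosages.

    ``frequencies`` defaults to the observed counted-allele frequencies of
    the input individuals (the set used to build G, training plus validation).
    """
    Z, ids = _dosages(genotypes)
    q = Z.mean(axis=0) / 2.0 if frequencies is None else np.asarray(frequencies, float)
    denom = float(2.0 * np.sum(q * (1.0 - q)))
    if denom <= 0.0:
        raise ValueError("all markers monomorphic: VanRaden denominator is zero")
    Zc = Z - 2.0 * q[None, :]
    G = (Zc @ Zc.T) / denom
    G = 0.5 * (G + G.T)  # kill rounding asymmetry
    return GMatrix(matrix=G, centering_frequencies=q, denominator=denom, individual_ids=ids)


def _restricted_neg2ll(h2, d, yt, xt, n):
    """-2 x restricted log-likelihood profiled over the total variance.

    ``d`` are eigenvalues of G, ``yt``/``xt`` the rotated response and
    intercept column.  V0 = h2 G + (1-h2) I has eigenvalues h2 d + 1 - h2.
    """
    v = h2 * d + (1.0 - h2)
    if np.any(v <= 0):
        return np.inf
    xvx = float(np.sum(xt * xt / v))
    mu = float(np.sum(xt * yt / v)) / xvx
    r2 = float(np.sum((yt - mu * xt) ** 2 / v))
    s2 = r2 / (n - 1)
    return (n - 1) * np.log(s2) + float(np.sum(np.log(v))) + np.log(xvx)


def reml_h2(
    y: np.ndarray, G: GMatrix | np.ndarray, tol: float = 1e-6
) -> VarianceComponents:
    """REML heritability under y = 1 mu + g + e with cov(g) = G sigma2_g.

    One eigendecomposition of G, then a grid scan plus bounded 1-D refinement
    of the restricted likelihood profile over h2 in [0, 1].  A flat profile
    (e.g. G = I, where sigma2_g and sigma2_e are unidentifiable) or an
    optimum at the boundary sets ``boundary=True``.
    """
    A = G.matrix if isinstance(G, GMatrix) else np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if A.shape != (n, n):
        raise ValueError(f"G is {A.shape}, y has {n} individuals")
    if n < 10:
        raise ValueError("need at least 10 individuals for REML")
    d, U = eigh(A)
    if d.min() < 1e-10:
        d, U = eigh(A + _JITTER * np.eye(n))
    yt = U.T @ y
    xt = U.T @ np.ones(n)
    lo, hi = 1e-6, 1.0 - 1e-6
    grid = np.linspace(lo, hi, 41)
    vals = np.array([_restricted_neg2ll(h, d, yt, xt, n) for h in grid])
    if not np.isfinite(vals).all():
        raise FloatingPointError("non-finite restricted likelihood")
    flat = vals.max() - vals.min() < 1e-8
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        _restricted_neg2ll, bounds=(a, b), args=(d, yt, xt, n),
        method="bounded", options={"xatol": tol},
    )
    h2 = float(res.x)
    neg2ll = float(res.fun)
    # profiled total variance at the optimum
    v = h2 * d + (1.0 - h2)
    xvx = float(np.sum(xt * xt / v))
    mu = float(np.sum(xt * yt / v)) / xvx
    s2 = float(np.sum((yt - mu * xt) ** 2 / v)) / (n - 1)
    boundary = flat or h2 < 1e-3 or h2 > 1.0 - 1e-3
    return VarianceComponents(
        genetic_variance=h2 * s2,
        residual_variance=(1.0 - h2) * s2,
        heritability=h2,
        log_likelihood=-0.5 * neg2ll,
        boundary=boundary,
    )


def gblup_predict(
    y_train: np.ndarray,
    G: GMatrix | np.ndarray,
    train_idx: np.ndarray,
    vc: VarianceComponents,
) -> np.ndarray:
    """GEBVs for every individual in G from training phenotypes only.

    Validation phenotypes are masked by construction: with V_tt = G_tt
    sigma2_g + I sigma2_e over the training block and the GLS mean mu-hat,

        g-hat = sigma2_g * G[:, train] V_tt^{-1} (y_train - mu-hat).

    Returns the n-vector of GEBVs (training and validation individuals).
    """
    A = G.matrix if isinstance(G, GMatrix) else np.asarray(G, dtype=float)
    train_idx = np.asarray(train_idx)
    y_train = np.asarray(y_train, dtype=float)
    if y_train.size != train_idx.size:
        raise ValueError("y_train and train_idx lengths differ")
    if vc.genetic_variance == 0.0:
        return np.zeros(A.shape[0])
    Gtt = A[np.ix_(train_idx, train_idx)]
    V = vc.genetic_variance * Gtt + vc.residual_variance * np.eye(train_idx.size)
    try:
        cf = cho_factor(V)
    except np.linalg.LinAlgError:
        try:
            cf = cho_factor(V + _JITTER * np.eye(train_idx.size))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("training variance matrix singular after jitter") from exc
    ones = np.ones(train_idx.size)
    vi_y = cho_solve(cf, y_train)
    vi_1 = cho_solve(cf, ones)
    mu = float(ones @ vi_y) / float(ones @ vi_1)
    w = cho_solve(cf, y_train - mu * ones)
    return vc.genetic_variance * (A[:, train_idx] @ w)
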
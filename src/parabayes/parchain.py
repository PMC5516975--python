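"""Multiple-chain orchestration and convergence diagnostics.

The parallel scheme follows the master/slave layout of multi-chain MCMC for
genomic prediction: burn-in cannot be parallelized, so every chain pays the
full burn-in and the post-burn-in sampling budget is divided equally (ceiling
division) across chains.  Chains are seeded deterministically from a master
seed, run independently (process-level parallelism via joblib when
``n_jobs > 1``), and their posterior-mean effects are pooled by an unweighted
average, from which GEBVs are computed.  Convergence across chains is judged
by the Gelman-Rubin shrink factor R-hat on the residual-variance traces.

To make the multi-chain diagnostic meaningful, each chain starts from a
different (overdispersed) initial residual variance drawn from its own seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from joblib import Parallel, delayed

from .genoio import GenotypeMatrix
from .mcmc import ChainSamples, PriorSpec, run_chain

__all__ = [
    "ChainPlan",
    "PooledPosterior",
    "plan_chains",
    "run_parallel",
    "gelman_rubin",
    "gebv_from_effects",
]


@dataclass(frozen=True)
class ChainPlan:
    """How a total MCMC iteration budget is split across parallel chains."""

    n_chains: int
    per_chain_burn_in: int
    per_chain_keep: int
    seeds: tuple[int, ...]
    total_budget: int


@dataclass
class PooledPosterior:
    """Pooled multi-chain posterior summaries."""

    pooled_effects: np.ndarray  # mean over chains of per-chain posterior-mean g_j
    pooled_mu: float
    per_chain_traces: list[np.ndarray]  # full residual-variance trace per chain
    shrink_factor: float  # R-hat on post-burn-in residual-variance traces (nan for 1 chain)
    gebv: np.ndarray
    chains: list[ChainSamples]

    @property
    def posterior_mean_pi(self) -> Optional[float]:
        vals = [c.posterior_mean_pi for c in self.chains]
        if any(v is None for v in vals):
            return None
        return float(np.mean(vals))


def plan_chains(
    total_budget: int, burn_in: int, n_chains: int, master_seed: int
) -> ChainPlan:
    """Split a total iteration budget over chains.

    Every chain runs the full ``burn_in`` plus ceil((total_budget - burn_in)
    / n_chains) kept iterations; per-chain seeds are spawned deterministically
    from ``master_seed``.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if not 0 <= burn_in < total_budget:
        raise ValueError("need 0 <= burn_in < total_budget")
    sampling = total_budget - burn_in
    if n_chains > sampling:
        raise ValueError(
            f"{n_chains} chains but only {sampling} post-burn-in iterations: "
            "fewer than one kept draw per chain"
        )
    keep = -(-sampling // n_chains)  # ceiling division
    ss = np.random.SeedSequence(master_seed)
    # draw extra values so pairwise-distinct seeds survive 31-bit collisions
    pool = [int(s) & 0x7FFFFFFF for s in ss.generate_state(2 * n_chains + 8, np.uint32)]
    seeds = list(dict.fromkeys(pool))[:n_chains]
    if len(seeds) < n_chains:
        raise RuntimeError("could not derive distinct chain seeds")
    return ChainPlan(
        n_chains=n_chains,
        per_chain_burn_in=burn_in,
        per_chain_keep=keep,
        seeds=tuple(seeds),
        total_budget=total_budget,
    )


def _one_chain(method, genotypes, y, prior, plan: ChainPlan, k: int,
               overdisperse: bool = True) -> ChainSamples:
    seed = plan.seeds[k]
    s2e_init = None
    if overdisperse:
        # overdispersed start: each chain's initial sigma2_e in [0.1, 1.1) * var(y)
        u = np.random.default_rng(seed ^ 0x5EED).random()
        s2e_init = (0.1 + u) * float(np.var(np.asarray(y, dtype=float)))
    return run_chain(
        method,
        genotypes,
        y,
        prior=prior,
        total_iter=plan.per_chain_burn_in + plan.per_chain_keep,
        burn_in=plan.per_chain_burn_in,
        seed=seed,
        s2e_init=s2e_init,
    )


def run_parallel(
    method: str,
    genotypes,
    y: np.ndarray,
    plan: ChainPlan,
    prior: PriorSpec | None = None,
    n_jobs: int = 1,
    overdisperse: bool = True,
) -> PooledPosterior:
    """Run the chains of ``plan`` independently and pool their posteriors.

    Results are identical whatever ``n_jobs`` is: chains share no mutable
    state and each is reproducible from its own seed.  Pooled effects are the
    unweighted mean of per-chain posterior-mean effects (chains keep equal
    draw counts by construction); GEBVs come from the pooled effects.
    """
    if prior is None:
        prior = PriorSpec.for_method(method)
    if prior.method == "bayesCpi" and prior.scale is None:
        # derive the common-variance scale once from the full data so every
        # chain (and any execution order) uses the same value
        Z = genotypes.dosages if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes, float)
        q = Z.mean(axis=0) / 2.0
        prior = PriorSpec(
            method=prior.method, nu=prior.nu,
            scale=prior.derive_scale(np.asarray(y, float), q),
            pi_zero=prior.pi_zero, residual_nu=prior.residual_nu,
            residual_scale=prior.residual_scale, n_mh=prior.n_mh,
        )
    if n_jobs == 1:
        chains = [
            _one_chain(method, genotypes, y, prior, plan, k, overdisperse)
            for k in range(plan.n_chains)
        ]
    else:
        chains = Parallel(n_jobs=n_jobs)(
            delayed(_one_chain)(method, genotypes, y, prior, plan, k, overdisperse)
            for k in range(plan.n_chains)
        )
    pooled = np.mean([c.posterior_mean_effects for c in chains], axis=0)
    pooled_mu = float(np.mean([c.posterior_mean_mu for c in chains]))
    rhat = float("nan")
    if plan.n_chains >= 2:
        rhat = gelman_rubin([c.residual_variance_trace for c in chains])
    gebv = gebv_from_effects(genotypes, pooled)
    return PooledPosterior(
        pooled_effects=pooled,
        pooled_mu=pooled_mu,
        per_chain_traces=[c.full_residual_trace for c in chains],
        shrink_factor=rhat,
        gebv=gebv,
        chains=list(chains),
    )


def gelman_rubin(traces: Sequence[np.ndarray]) -> float:
    """Gelman-Rubin shrink factor R-hat for one scalar quantity.

    With m chains of length n, B = n * var(chain means), W = mean of
    within-chain variances, V-hat = ((n-1)/n) W + B/n and
    R-hat = sqrt(V-hat / W).  R-hat near 1 indicates the chains have mixed
    into a common distribution.
    """
    traces = [np.asarray(t, dtype=float) for t in traces]
    if len(traces) < 2:
        raise ValueError("need at least two chains")
    n = traces[0].size
    if n < 2 or any(t.size != n for t in traces):
        raise ValueError("chains must have equal lengths >= 2")
    means = np.array([t.mean() for t in traces])
    within = np.array([t.var(ddof=1) for t in traces])
    W = within.mean()
    B = n * means.var(ddof=1)
    if W == 0.0:
        if B == 0.0:
            return 1.0  # all chains constant and equal
        raise ValueError("chains are constant but unequal; R-hat undefined")
    vhat = (n - 1) / n * W + B / n
    return float(np.sqrt(vhat / W))


def gebv_from_effects(
    genotypes,
    effects: np.ndarray,
    effect_marker_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """GEBV_i = sum_j Z_ij g_j with the training allele coding.

    When ``effect_marker_ids`` is given and ``genotypes`` is a
    :class:`GenotypeMatrix`, marker sets must match exactly (same ids, same
    order); mismatches raise with the offending ids listed.
    """
    effects = np.asarray(effects, dtype=float)
    if isinstance(genotypes, GenotypeMatrix):
        Z = genotypes.dosages
        if effect_marker_ids is not None:
            gm = list(genotypes.marker_ids)
            em = list(effect_marker_ids)
            if gm != em:
                bad = sorted(set(gm).symmetric_difference(em)) or ["<order differs>"]
                raise ValueError(f"marker sets not aligned: {bad[:10]}")
    else:
        Z = np.asarray(genotypes, dtype=float)
    if Z.shape[1] != effects.size:
        raise ValueError(
            f"{Z.shape[1]} genotype markers but {effects.size} effects"
        )
    return Z @ effects
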
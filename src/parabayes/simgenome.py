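"""Forward-in-time Wright-Fisher simulator for genomic-prediction benchmarks.

A diploid population of constant size undergoes discrete generations of
random mating (distinct parents, one gamete each), recombination under the
Haldane model (crossover count Poisson in the chromosome's Morgan length,
crossover positions uniform) and recurrent allele-flip mutation at a
per-locus, per-gamete, per-generation rate.  Linkage disequilibrium among
markers therefore arises from drift, recombination and mutation alone.

Each chromosome carries a marker panel plus a set of QTL-candidate loci that
mutate at their own rate and are excluded from the marker panel.  After the
final population is drawn, a trait is built by picking QTL uniformly among
the segregating candidate loci, drawing i.i.d. standard-normal allele
substitution effects, and adding Gaussian environmental noise scaled so that
the target heritability h2 = var(TBV)/var(phenotype) holds in expectation:
sigma2_env = var(TBV) (1 - h2) / h2.

Defaults mirror a common cattle-breeding simulation setup: a small
historical population (Ne = 100) run 1000 generations to drift-mutation
equilibrium, 1-Morgan chromosomes, mutation rate 1.25e-3, final population
of 1000 and h2 = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .genoio import GenotypeMatrix

__all__ = ["SimConfig", "SimOutput", "HaploPop", "simulate_history",
           "draw_final_population", "assign_trait", "simulate"]


@dataclass(frozen=True)
class SimConfig:
    n_individuals: int = 1000
    n_chromosomes: int = 10
    loci_per_chromosome: int = 10_000
    chromosome_length: float = 1.0  # Morgans
    marker_mutation_rate: float = 1.25e-3
    qtl_mutation_rate: float = 1.25e-3
    n_qtl_per_chromosome: int = 50
    heritability: float = 0.5
    n_historical_generations: int = 1000
    historical_pop_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.heritability <= 1.0:
            raise ValueError("heritability must lie in (0, 1]")
        for name in ("n_individuals", "n_chromosomes", "loci_per_chromosome",
                     "n_qtl_per_chromosome", "n_historical_generations",
                     "historical_pop_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("marker_mutation_rate", "qtl_mutation_rate"):
            r = getattr(self, name)
            if not 0.0 <= r < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.chromosome_length < 0:
            raise ValueError("chromosome_length must be >= 0")


@dataclass
class HaploPop:
    """A phased diploid population over the full locus set (markers + QTL candidates)."""

    haplotypes: np.ndarray  # (N, 2, L) int8 allele states
    chromosome: np.ndarray  # (L,) int, 1-based
    position_morgans: np.ndarray  # (L,) within-chromosome position
    is_qtl_candidate: np.ndarray  # (L,) bool

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    @property
    def dosages(self) -> np.ndarray:
        return self.haplotypes.sum(axis=1).astype(float)

    @property
    def allele_frequency(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1))

    def segregating(self) -> np.ndarray:
        f = self.allele_frequency
        return (f > 0.0) & (f < 1.0)

    def to_genotype_matrix(self, markers_only: bool = True) -> GenotypeMatrix:
        keep = ~self.is_qtl_candidate if markers_only else np.ones(self.n_loci, bool)
        idx = np.flatnonzero(keep)
        bp = np.round(self.position_morgans * 1e8).astype(np.int64) + 1
        return GenotypeMatrix(
            individual_ids=[f"id{i + 1}" for i in range(self.n_individuals)],
            marker_ids=[
                f"chr{self.chromosome[j]}_{'q' if self.is_qtl_candidate[j] else 'm'}{j}"
                for j in idx
            ],
            chromosome=self.chromosome[idx],
            position=bp[idx],
            dosages=self.dosages[:, idx],
            a1=["A"] * idx.size,
            a2=["G"] * idx.size,
        )


@dataclass
class SimOutput:
    """Simulated genotypes, trait architecture and phenotypes."""

    genotypes: GenotypeMatrix  # marker panel (QTL-candidate loci excluded)
    qtl_indices: np.ndarray  # indices into the full locus set
    qtl_effects: np.ndarray
    qtl_dosages: np.ndarray  # individuals x QTL, for truth checks
    true_breeding_values: np.ndarray
    phenotypes: np.ndarray
    realized_heritability: float
    qtl_chromosome: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    qtl_position: np.ndarray = field(default_factory=lambda: np.empty(0))


@njit(cache=True)
def _rpois(rng, lam):
    # Knuth's algorithm; lam is a chromosome length in Morgans (small)
    if lam <= 0.0:
        return 0
    L = np.exp(-lam)
    k = 0
    p = 1.0
    while True:
        p *= rng.random()
        if p <= L:
            return k
        k += 1


@njit(cache=True)
def _meiosis(rng, haps, pairs, positions, chrom_start, chrom_len, out):
    """Produce offspring haplotypes by Haldane-model recombination.

    ``haps`` is the parental (P, 2, L) array, ``pairs`` the (N, 2) parent
    indices (one gamete from each), ``chrom_start`` the locus offsets per
    chromosome (length C+1).
    """
    n_off = pairs.shape[0]
    n_chrom = chrom_len.shape[0]
    cx = np.empty(64)
    for i in range(n_off):
        for g in range(2):
            p = pairs[i, g]
            for c in range(n_chrom):
                s = chrom_start[c]
                e = chrom_start[c + 1]
                k = _rpois(rng, chrom_len[c])
                if k > 64:
                    k = 64
                for t in range(k):
                    cx[t] = rng.random() * chrom_len[c]
                # insertion sort of the k crossover positions
                for t in range(1, k):
                    v = cx[t]
                    u = t - 1
                    while u >= 0 and cx[u] > v:
                        cx[u + 1] = cx[u]
                        u -= 1
                    cx[u + 1] = v
                h = 0 if rng.random() < 0.5 else 1
                ptr = 0
                for l in range(s, e):
                    while ptr < k and positions[l] > cx[ptr]:
                        h = 1 - h
                        ptr += 1
                    out[i, g, l] = haps[p, h, l]
    return out


def _mutate(rng: np.random.Generator, haps: np.ndarray, marker_idx: np.ndarray,
            qtl_idx: np.ndarray, u_marker: float, u_qtl: float) -> None:
    """Recurrent allele-flip mutation, in place, one generation."""
    n_gam = haps.shape[0] * 2
    for idx, rate in ((marker_idx, u_marker), (qtl_idx, u_qtl)):
        if rate <= 0.0 or idx.size == 0:
            continue
        n_mut = rng.binomial(n_gam * idx.size, rate)
        if n_mut == 0:
            continue
        gi = rng.integers(0, n_gam, n_mut)
        li = idx[rng.integers(0, idx.size, n_mut)]
        flat = haps.reshape(n_gam, haps.shape[2])
        flat[gi, li] ^= 1


def _n_candidates_per_chromosome(config: SimConfig) -> int:
    # oversample candidate loci so enough still segregate after drift
    return int(np.ceil(1.5 * config.n_qtl_per_chromosome)) + 2


def _locus_layout(config: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chromosome index, Morgan position and QTL-candidate flag per locus.

    Candidate loci are spread evenly through each chromosome's locus order so
    QTL sit inside the marker map, not at its ends.
    """
    n_cand = _n_candidates_per_chromosome(config)
    per = config.loci_per_chromosome + n_cand
    chrom = np.repeat(np.arange(1, config.n_chromosomes + 1), per)
    within = np.tile(np.arange(per), config.n_chromosomes)
    pos = (within + 0.5) / per * config.chromosome_length
    cand_local = np.round((np.arange(n_cand) + 0.5) / n_cand * per).astype(int)
    cand_local = np.clip(cand_local, 0, per - 1)
    is_cand = np.zeros(per, bool)
    is_cand[cand_local] = True
    return chrom, pos, np.tile(is_cand, config.n_chromosomes)


def _advance(rng: np.random.Generator, pop: HaploPop, n_offspring: int,
             config: SimConfig) -> HaploPop:
    """One generation of random mating with recombination and mutation."""
    n_par = pop.n_individuals
    mothers = rng.integers(0, n_par, n_offspring)
    if n_par > 1:
        shift = rng.integers(1, n_par, n_offspring)
        fathers = (mothers + shift) % n_par  # distinct from mother
    else:
        fathers = mothers.copy()
    pairs = np.stack([mothers, fathers], axis=1)
    chrom_start = np.searchsorted(
        pop.chromosome, np.arange(1, config.n_chromosomes + 2)
    ).astype(np.int64)
    chrom_len = np.full(config.n_chromosomes, config.chromosome_length)
    out = np.empty((n_offspring, 2, pop.n_loci), dtype=np.int8)
    _meiosis(rng, pop.haplotypes, pairs, pop.position_morgans, chrom_start,
             chrom_len, out)
    child = HaploPop(out, pop.chromosome, pop.position_morgans, pop.is_qtl_candidate)
    marker_idx = np.flatnonzero(~pop.is_qtl_candidate)
    qtl_idx = np.flatnonzero(pop.is_qtl_candidate)
    _mutate(rng, child.haplotypes, marker_idx, qtl_idx,
            config.marker_mutation_rate, config.qtl_mutation_rate)
    return child


def simulate_history(
    config: SimConfig,
    base_init: str = "random",
    require_segregating: bool = True,
) -> HaploPop:
    """Run the historical population to drift-mutation equilibrium.

    The base population starts at allele frequency 0.5 (``base_init="random"``:
    haplotype alleles i.i.d. Bernoulli(0.5)) or fixed (``"monomorphic"``) and
    is advanced ``n_historical_generations`` generations at constant size
    ``historical_pop_size``.  Loci fixed at the end stay in the matrix as
    monomorphic columns.
    """
    chrom, pos, is_cand = _locus_layout(config)
    rng = np.random.default_rng([config.seed, 0])
    N, L = config.historical_pop_size, chrom.size
    if base_init == "random":
        haps = rng.integers(0, 2, size=(N, 2, L), dtype=np.int8)
    elif base_init == "monomorphic":
        haps = np.zeros((N, 2, L), dtype=np.int8)
    else:
        raise ValueError("base_init must be 'random' or 'monomorphic'")
    pop = HaploPop(haps, chrom, pos, is_cand)
    for _ in range(config.n_historical_generations):
        pop = _advance(rng, pop, N, config)
    if require_segregating and not pop.segregating().any():
        raise RuntimeError(
            "no segregating loci after the historical phase; increase the "
            "mutation rate or reduce n_historical_generations / drift"
        )
    return pop


def draw_final_population(ancestral: HaploPop, config: SimConfig) -> HaploPop:
    """Draw the final population by one round of random mating from the last
    historical generation (recombination and mutation still apply)."""
    if ancestral.n_individuals == 0:
        raise ValueError("ancestral population is empty")
    rng = np.random.default_rng([config.seed, 1])
    return _advance(rng, ancestral, config.n_individuals, config)


def assign_trait(population: HaploPop, config: SimConfig) -> SimOutput:
    """Pick QTL, draw effects and phenotypes at the target heritability.

    QTL are chosen uniformly among *segregating* QTL-candidate loci; their
    allele-substitution effects are i.i.d. N(0, 1).  Environmental noise has
    variance var(TBV) (1 - h2) / h2, so the realized heritability
    var(TBV)/var(phenotype) is centered on the target.
    """
    rng = np.random.default_rng([config.seed, 2])
    n_qtl = config.n_chromosomes * config.n_qtl_per_chromosome
    cand = np.flatnonzero(population.is_qtl_candidate & population.segregating())
    if cand.size < n_qtl:
        raise RuntimeError(
            f"only {cand.size} segregating QTL-candidate loci for {n_qtl} QTL; "
            "increase mutation rate or candidate count"
        )
    qtl = np.sort(rng.choice(cand, size=n_qtl, replace=False))
    effects = rng.standard_normal(n_qtl)
    qtl_dos = population.dosages[:, qtl]
    tbv = qtl_dos @ effects
    var_tbv = float(np.var(tbv))
    if np.ptp(tbv) == 0.0 or var_tbv == 0.0:
        raise RuntimeError("true breeding values have zero variance (degenerate trait)")
    h2 = config.heritability
    if h2 == 1.0:
        noise = np.zeros_like(tbv)
    else:
        noise = rng.normal(0.0, np.sqrt(var_tbv * (1.0 - h2) / h2), tbv.size)
    pheno = tbv + noise
    return SimOutput(
        genotypes=population.to_genotype_matrix(markers_only=True),
        qtl_indices=qtl,
        qtl_effects=effects,
        qtl_dosages=qtl_dos,
        true_breeding_values=tbv,
        phenotypes=pheno,
        realized_heritability=var_tbv / float(np.var(pheno)),
        qtl_chromosome=population.chromosome[qtl],
        qtl_position=population.position_morgans[qtl],
    )


def simulate(config: SimConfig) -> SimOutput:
    """History -> final population -> trait, reproducible from ``config.seed``."""
    ancestral = simulate_history(config)
    final = draw_final_population(ancestral, config)
    return assign_trait(final, config)
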
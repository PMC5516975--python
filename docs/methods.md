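# Methods

## Model and samplers

All whole-genome regressions fit `y_i = μ + Σ_j Z_ij α_j + e_i` with raw
0/1/2 dosage coding (no column centering; the sampled overall mean μ absorbs
the dosage means).  The residual vector `e = y − μ − Zα` is maintained
incrementally: every update of μ or of one α_j patches `e` in place, so a
full iteration costs O(nM).  Because dosages are small integers, the
float32 genotype rows introduce no rounding in these updates; a consistency
test bounds the drift of `e` after 1000 iterations at 1e-6.

Full conditionals:

* `μ | ·  ~  N(mean(y − Zα), σ²_e/n)`.
* `α_j | ·  ~  N(ĉ, C)` with `C = σ²_e/(z_j′z_j + σ²_e/σ²_αj)` and
  `ĉ = z_j′(e + z_j α_j^old) / (z_j′z_j + σ²_e/σ²_αj)`.  A marker with
  `z_j′z_j = 0` falls back to its prior.
* BayesA locus variance: `σ²_αj = (νS + α_j²)/χ²_{ν+1}` (scaled inverse
  chi-square, ν = 4.012, S = 0.0020).
* BayesB (ν = 4.234, S = 0.0429, π = 0.99): the locus variance is sampled by
  Metropolis–Hastings with the effect integrated out.  Candidates come from
  the prior mixture (0 with probability π, else `νS/χ²_ν`); the acceptance
  ratio compares `N(r_j; 0, (z′z)²σ² + z′z σ²_e)` between candidate and
  current σ², where `r_j = z_j′(e + z_j α_j)`.  Default 10 MH cycles per
  locus per iteration (configurable); the effect is then drawn from its
  normal conditional when σ² > 0, else set to 0.
* BayesCπ (ν = 4.2): inclusion indicators use the same marginal-likelihood
  ratio with prior odds `(1−π)/π`; the common variance is
  `(νS + Σ_incl α_j²)/χ²_{ν+m₁}`; `π ~ Beta(m₀+1, m₁+1)` (uniform prior).
  The scale S is derived once at startup by allocating half the phenotypic
  variance to the expected non-zero fraction:
  `S = σ̃²(ν−2)/ν`, `σ̃² = 0.5·var(y) / ((1−π₀)·Σ_j 2q_j(1−q_j))` at
  π₀ = 0.99.  It can be overridden via `PriorSpec(scale=...)`.
* Residual variance: flat prior by default (ν_e = −2, S_e = 0), giving
  `σ²_e = e′e/χ²_{n−2}`; both parameters are configurable.

Update order is fixed for reproducibility: μ, loci in ascending index,
variances, then π.  Initialization: effects 0, locus variances at S,
σ²_e = 0.5·var(y), π at its fixed value (BayesB) or 0.5 (BayesCπ).  Chains
are aborted with the iteration index if the state becomes non-finite.

Sampler correctness is established three ways: empirical moments of every
full conditional against closed forms (1% at 1e5–1e6 draws); each method's
posterior-mean effect on a 1-marker, n = 5 dataset against a dense 2-D
quadrature over (σ²_α, σ²_e) with μ and α integrated analytically (2%);
and BayesB at π = 0 against BayesA with matched (ν, S).

## Parallel chains

Burn-in cannot be parallelized, so a total budget B with burn-in b run on k
chains costs each chain `b + ceil((B−b)/k)` iterations; kept draws are
pooled by an unweighted average of per-chain posterior-mean effects (equal
keep counts by construction).  Chain seeds are spawned deterministically
from a master seed (distinct 31-bit values), so results are bit-identical
whether chains run sequentially or in worker processes (joblib,
`n_jobs > 1`).

Each chain starts from an overdispersed initial residual variance
(`[0.1, 1.1)·var(y)`, derived from its own seed) so that the Gelman–Rubin
diagnostic is informative rather than trivially 1.  `R̂ = sqrt(V̂/W)` with
`V̂ = ((n−1)/n)W + B/n` (no degrees-of-freedom correction), where B/n is
the variance of chain means and W the mean within-chain variance; all-equal
constant chains define R̂ = 1, unequal constant chains are an error.
`run_parallel(..., overdisperse=False)` restores the single-chain
initialization, making one-chain pooling bit-identical to `run_chain`.

## GBLUP and REML

`G = ZZ′/(2Σq_i(1−q_i))` with Z centered at twice the observed
counted-allele frequencies of the genotype set used to build G (training
plus validation).  REML under `y = 1μ + g + e` is profiled to one dimension:
after a single eigendecomposition of G, the restricted log-likelihood at a
given h² is O(n), and a 41-point grid scan plus bounded Brent refinement
(tolerance 1e-6) maximizes it on [0, 1].  A flat profile (e.g. G = I, where
σ²_g and σ²_e are not separately identifiable) or a boundary optimum sets a
`boundary` flag.  A jitter of 1e-8 is added to G's diagonal when its
smallest eigenvalue is below 1e-10 (near-duplicate individuals).  Prediction
solves the conditional-mean equations on the training block,
`ĝ = σ²_g G[:,t] (G_tt σ²_g + I σ²_e)⁻¹ (y_t − μ̂)` with the GLS mean μ̂, so
validation phenotypes are masked by construction.  The central correctness
oracle is the exact equivalence of GBLUP GEBVs with ridge-regression
SNP-BLUP (per-marker variance σ²_g/denominator) on random small instances.

## Cross-validation and the accuracy criterion

Random near-equal k-fold partitions (k = 5 default), redrawn per repeat;
every individual is validated exactly once per repeat with its phenotype
masked.  The headline statistic is the mean over folds × repeats of the
validation-set Pearson correlation r between GEBV and corrected phenotype,
scaled to `r/√h²`; its dispersion is the SD of those per-fold correlations
on the same scale.  Correlations are always computed **within** a
validation set: GEBVs predicted from different training sets carry
arbitrary additive offsets (breeding values have no origin), so
concatenating folds before correlating mixes those offsets into the
statistic as pure noise.  For the same reason the per-individual GEBVs
returned for inspection are centered within each fold before averaging
over repeats; on simulated data the correlation of these with the true
breeding values is reported alongside the headline criterion.

h² for the scaling is estimated once on the full data by G-matrix REML and
shared by all methods on a trait; for GBLUP the same full-data variance
components are reused across training folds (per-fold REML changes
accuracies by less than Monte-Carlo noise at these scales and triples the
cost).  The comparison report formats trait × method cells as
`value(SD)` to three decimals with a per-method mean row.

## Simulator

A diploid Wright–Fisher population of constant size (default 100) is run
for 1000 discrete generations of random mating (distinct parents, one
gamete each): enough, at the default flip-mutation rate of 1.25e-3 per
locus per gamete per generation (θ = 4N_e·u = 0.5), to reach
mutation–drift equilibrium from the Bernoulli(0.5) base population.
Recombination follows the Haldane model — crossover counts Poisson in the
chromosome's Morgan length (default 1), positions uniform — so marker LD
emerges from drift, recombination and mutation alone.  The final population
(default 1000) is one further round of random mating.  The marginal
allele-frequency process is validated against an independent single-locus
Wright–Fisher simulation (spectrum and heterozygosity).

Each chromosome carries its marker panel plus QTL-candidate loci mutating
at their own rate and excluded from the marker panel.  Candidates are
oversampled (⌈1.5·n_qtl⌉+2 per chromosome) so that the required number
still segregates after drift.  QTL are drawn uniformly among segregating
candidates, effects are i.i.d. N(0,1), and environmental noise has variance
`var(TBV)(1−h²)/h²`, centering the realized h² = var(TBV)/var(phenotype) on
the target (within ±0.03 across seeds at h² = 0.5).  A constant TBV vector
(degenerate trait) raises an error rather than emitting an undefined
heritability.

What the simulator does **not** emulate: selection, migration, pedigree or
family structure beyond one generation of random mating, dominance or
epistasis, sex chromosomes, genotyping error and missingness, and the
ascertainment bias of commercial SNP chips.  Passing tests on these data
therefore demonstrate correctness of the estimators and the parallel
machinery, not field performance on real cattle data, where LD structure
and confounding are less benign.

## Benchmark scales

The heavier statistical tests and `scripts/acceptance.py` use a reduced
scale chosen as this package's standard benchmark: 1000 individuals, five
1-Morgan chromosomes × 400 markers (~2000 markers, essentially all
segregating), 50 QTL, h² = 0.5; MCMC budgets of 3000–12000 iterations with
1000–2500 burn-in.  The full-scale protocol (10 chromosomes × 10000
markers, 50000 iterations with 5000 burn-in, up to 18 chains) is supported
by the same code paths and configuration objects.  At the reduced scale the
chain-count spread of cross-validated accuracy is dominated by Monte-Carlo
noise of the per-fold correlations (a few tenths of a percentage point with
10000 kept draws); it shrinks with kept draws, and the invariance bound
checked in the tests is max−min ≤ 0.01 across 1/2/4 chains.

## Numerical and degenerate-input policy

Genotype dosages are held as float (nan = missing before imputation);
mean imputation is the only missing-data handling.  The HWE exact test
enumerates the conditional heterozygote distribution in log space
(two-sided, no mid-p).  OLS pre-adjustment of phenotypes uses reference-
level dummy coding with a pivoted-QR check that names aliased factor levels
on rank deficiency; corrected phenotypes are residuals (mean zero) since
downstream models carry their own μ.  Ties and order: marker updates in
ascending index; fold assignment by permutation + contiguous blocks;
formatting rounds half-even via Python's f-strings.
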
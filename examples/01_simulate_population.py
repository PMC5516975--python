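"""Simulate a genotyped population with a heritable trait.

A small historical population drifts to mutation-drift equilibrium, a final
population of 800 is drawn from it, and an additive trait with 30 QTL at
heritability 0.5 is layered on top.
"""

import numpy as np

import parabayes as pb

cfg = pb.SimConfig(
    n_individuals=800,
    n_chromosomes=3,
    loci_per_chromosome=300,
    n_qtl_per_chromosome=10,
    heritability=0.5,
    n_historical_generations=500,
    historical_pop_size=100,
    seed=1,
)
out = pb.simulate(cfg)

f = out.genotypes.counted_allele_frequency
maf = np.minimum(f, 1 - f)
print(f"individuals:            {out.genotypes.n_individuals}")
print(f"markers:                {out.genotypes.n_markers}")
print(f"segregating markers:    {int(((f > 0) & (f < 1)).sum())}")
print(f"mean MAF (segregating): {maf[(f > 0) & (f < 1)].mean():.3f}")
print(f"QTL:                    {out.qtl_effects.size}")
print(f"realized heritability:  {out.realized_heritability:.3f}")
# The realized value is var(TBV)/var(phenotype) in this finite sample, so it
# scatters around the 0.5 target; the trait is fully additive.
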
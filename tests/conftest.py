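import numpy as np
import pytest

import parabayes as pb

# Reduced benchmark scale used by the heavier statistical tests: 1000
# individuals, ~2000 markers on 5 one-Morgan chromosomes, 50 QTL, h2 = 0.5.
REDUCED = dict(
    n_individuals=1000,
    n_chromosomes=5,
    loci_per_chromosome=400,
    n_qtl_per_chromosome=10,
    chromosome_length=1.0,
    heritability=0.5,
    n_historical_generations=1000,
    historical_pop_size=100,
)


@pytest.fixture(scope="session")
def small_sim() -> pb.SimOutput:
    """A quick 300 x 300 simulated dataset for functional tests."""
    cfg = pb.SimConfig(
        n_individuals=300,
        n_chromosomes=2,
        loci_per_chromosome=150,
        n_qtl_per_chromosome=15,
        n_historical_generations=200,
        historical_pop_size=100,
        seed=42,
    )
    return pb.simulate(cfg)


@pytest.fixture(scope="session")
def reduced_sim() -> pb.SimOutput:
    """The reduced benchmark dataset (h2 = 0.5) shared by the statistical tests."""
    return pb.simulate(pb.SimConfig(seed=20250901, **REDUCED))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
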
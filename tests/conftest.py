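import numpy as np
import pytest

from neurofactors import simulate as sim


@pytest.fixture(scope="session")
def measurement_cohort():
    """Items + factors from the default bifactor model, no genetics (h2 = 0)."""
    cfg = sim.SimulationConfig(
        n_individuals=60_000, n_snps=10, h2=(0.0, 0.0, 0.0), seed=2024
    )
    factors = sim.simulate_factors(None, cfg)
    items = sim.simulate_items(factors, cfg)
    return cfg, factors, items


@pytest.fixture(scope="session")
def small_genetic_cohort():
    """A modest genotyped cohort shared across GWAS/LDSC/loci/PRS unit tests."""
    cfg = sim.SimulationConfig(n_individuals=4_000, n_snps=2_000, seed=77)
    genotypes = sim.simulate_genotypes(cfg)
    factors = sim.simulate_factors(genotypes, cfg)
    return cfg, genotypes, factors


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
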
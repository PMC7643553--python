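import numpy as np
import pytest

from palmlnc.simulate import (
    SimulationConfig,
    simulate_all,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=1, n_individuals=60, n_snps=300)


@pytest.fixture(scope="session")
def bundle(small_config):
    """One full synthetic study shared by read-only tests."""
    return simulate_all(small_config)


@pytest.fixture(scope="session")
def genotypes_200():
    """A 200-individual structured genotype panel (study-scale)."""
    cfg = SimulationConfig(seed=7, n_individuals=200, n_snps=800)
    return cfg, simulate_genotypes(cfg)
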
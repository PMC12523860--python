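import numpy as np
import pytest

from pleionet import qc, simulate
from pleionet.datatypes import SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_animals=300, n_snps=1000, n_chromosomes=5, seed=7)


@pytest.fixture(scope="session")
def small_study(small_config):
    """A small simulated study shared by read-only tests."""
    geno = simulate.simulate_genotypes(small_config)
    qtl = simulate.assign_qtl_effects(geno.snp_map, small_config)
    pheno, truth = simulate.simulate_phenotypes(geno, qtl, small_config)
    pheno, _ = qc.build_contemporary_groups(pheno)
    return geno, qtl, pheno, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
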
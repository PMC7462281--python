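import numpy as np
import pytest

from eqtlkit import SimulationConfig, simulate_expression, simulate_genotypes


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_samples=150,
        n_variants=1200,
        n_genes=30,
        block_size=20,
        seed=11,
        secondary_fraction=0.2,
        cluster_specs=(3,),
        effect_r2=0.25,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    geno = simulate_genotypes(small_config)
    expr, cov, truth = simulate_expression(geno, small_config)
    return geno, expr, cov, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
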
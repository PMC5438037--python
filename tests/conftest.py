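import numpy as np
import pytest

from pwaskit import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A small null study reused by read-only tests."""
    cfg = SimulationConfig(
        n_cases=200,
        n_controls=200,
        n_genes=30,
        snps_per_gene=3,
        n_pathways=8,
        genes_per_pathway=3,
        n_causal_pathways=0,
        causal_snps_per_pathway=0,
        effect_size_beta=0.0,
        missing_rate=0.01,
        seed=11,
    )
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
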
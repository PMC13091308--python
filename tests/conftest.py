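import numpy as np
import pytest

from crossgwas.simulate import SimulationConfig, default_blocks, simulate_study


@pytest.fixture(scope="session")
def small_scene():
    """Desk-scale polygenic scene: 2,000 SNPs, 50 genes, 4 sets."""
    cfg = SimulationConfig(
        m_snps=2_000,
        blocks=default_blocks(2_000),
        seed=5,
        h2=(0.3, 0.3),
        rg_true=0.2,
        n_genes=50,
        genes_per_set=10,
        n_sets=4,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def null_scene():
    """Standard-size scene with zero heritability on both traits."""
    return simulate_study(SimulationConfig(seed=42, h2=(0.0, 0.0)))


@pytest.fixture(scope="session")
def null_gene_results(null_scene):
    from crossgwas.genes import run_gene_analysis

    return run_gene_analysis(
        null_scene.studies["trait_a"], null_scene.genes,
        null_scene.ld.corr_submatrix,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
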
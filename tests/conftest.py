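import numpy as np
import pytest

from modnet.synthetic import (
    SimulationConfig,
    simulate_compendium,
    simulate_gene_annotations,
    simulate_genotypes_and_effects,
    simulate_markers,
    simulate_regulatory_network,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        n_datasets=3,
        n_genes=300,
        n_samples_per_dataset=120,
        n_modules=6,
        module_size_range=(10, 15),
        frac_planted_gene_assoc=0.02,
        planted_module_pairs=[(0, 1, 1), (2, 3, -1)],
        n_variants=60,
        n_cis=8,
        n_trans=4,
        n_meth_bins=40,
        n_meth_coupled=4,
        n_tfs=12,
        n_random_edges=60,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """(datasets, catalog, truth) for a small planted compendium."""
    return simulate_compendium(small_cfg)


@pytest.fixture(scope="session")
def genetics_sim(small_cfg):
    """Compendium plus genotypes, methylation, network, markers and truth."""
    datasets, catalog, truth = simulate_compendium(small_cfg)
    anns = simulate_gene_annotations(small_cfg)
    genotypes, bins, truth = simulate_genotypes_and_effects(
        small_cfg, anns, datasets[0], truth
    )
    priors, tfs, truth = simulate_regulatory_network(small_cfg, catalog, truth)
    markers, truth = simulate_markers(small_cfg, catalog, truth)
    return dict(
        cfg=small_cfg, datasets=datasets, catalog=catalog, truth=truth,
        annotations=anns, genotypes=genotypes, bins=bins, priors=priors,
        tfs=tfs, markers=markers,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
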
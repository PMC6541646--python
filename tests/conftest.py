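"""Shared fixtures: a small synthetic population reused across test modules."""

import pytest

from phagepan.simulate import SimConfig, simulate_population


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A scaled-down population: same structure as the default study
    conditions (4 unequal groups, nested RBP lineages, 6/5 genotypes) but
    fast enough to rebuild pipelines repeatedly."""
    return SimConfig(
        genomes_per_group=(6, 4, 2, 2),
        genes_per_genome=(15, 20),
        group_pool_size=40,
        shared_pool_size=8,
        core_genes_per_group=5,
        n_strains=12,
        eps_genes_range=(6, 9),
        rgp_genes_range=(6, 9),
        eps_pool_size=20,
        rgp_pool_size=20,
        protein_length_range=(80, 150),
        seed=1,
    )


@pytest.fixture(scope="session")
def small_population(small_config):
    return simulate_population(small_config)
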
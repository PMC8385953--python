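import pytest

from cksrna import SimulationConfig, run_pipeline, simulate_dataset


@pytest.fixture(scope="session")
def noise_free_cfg():
    """Study-condition configuration: noise 0, fourfold induction, 20
    planted ck-sRNAs and 20 planted downregulated targets per direction."""
    return SimulationConfig(seed=1, noise_read_fraction=0.0)


@pytest.fixture(scope="session")
def dataset(noise_free_cfg):
    return simulate_dataset(noise_free_cfg)


@pytest.fixture(scope="session")
def result(dataset):
    return run_pipeline(dataset=dataset)


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced-scale configuration for generator-focused tests."""
    return SimulationConfig(
        seed=7, plant_genome_len=12_000, fungal_genome_len=6_000,
        n_plant_mirna_loci=3, n_plant_sirna24_loci=3,
        n_fungal_loci_26=2, n_fungal_loci_29_30=2,
        n_ck_srnas_per_direction=6, depth_per_sample=3_000,
        n_plant_genes=60, n_fungal_genes=50,
        noise_read_fraction=0.05,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return simulate_dataset(small_cfg)
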
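import pytest

from ernaflow.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def reference_config() -> SimulationConfig:
    """The reference study conditions: 10-Mb toy genome, ~200 enhancers,
    3+3 replicates, 8-fold induction, baseline mean 100 reads/strand."""
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(reference_config):
    return simulate_dataset(reference_config)


@pytest.fixture(scope="session")
def pipeline_result(dataset):
    from ernaflow.pipeline import run_pipeline

    return run_pipeline(dataset)


def small_null_config(seed: int) -> SimulationConfig:
    """A compact no-effect configuration for null-calibration sweeps."""
    return SimulationConfig(
        seed=seed,
        frac_induced=0.0,
        frac_repressed=0.0,
        n_chromosomes=1,
        chrom_length_bp=5_000_000,
        n_enhancers=120,
        n_genes=40,
        n_decoys=12,
        n_chirp_sites=12,
        n_chirp_decoys=4,
        contamination_sites=2,
    )
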
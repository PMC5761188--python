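import pytest

from rareburden.burden import run_full_analysis
from rareburden.simulate import (
    GeneSimSettings,
    SimulationConfig,
    simulate_cohort,
    spike_fixture_variants,
)


def null_config(seed: int = 11, **kwargs) -> SimulationConfig:
    """Study-sized cohort with zero background carrier rates."""
    return SimulationConfig(
        default_gene=GeneSimSettings(0.0, 0.0, 1.0, 1.0), seed=seed, **kwargs
    )


@pytest.fixture(scope="session")
def spiked_dataset():
    """A 1043/944 cohort carrying exactly the packaged LoF variant list."""
    dataset, truth = simulate_cohort(null_config())
    spike_fixture_variants(dataset, truth)
    return dataset, truth


@pytest.fixture(scope="session")
def spiked_report(spiked_dataset):
    dataset, _ = spiked_dataset
    return run_full_analysis(dataset)
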
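import warnings

import pytest

from zfmeth import SimulationConfig
from zfmeth.pipeline import PipelineConfig, run_pipeline


def small_sim_config(**overrides) -> SimulationConfig:
    """A fast two-chromosome configuration used across tests."""
    base = dict(
        seed=7,
        n_chromosomes=2,
        chromosome_length=150_000,
        n_sites=40,
        n_genes=60,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return small_sim_config()


@pytest.fixture(scope="session")
def small_dataset(small_config):
    from zfmeth import simulate_dataset

    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def reference_run():
    """Full pipeline at the default reference conditions (seed 42)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(PipelineConfig(seed=42, n_permutations=300))
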
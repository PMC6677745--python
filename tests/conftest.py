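import numpy as np
import pytest

from chromtraj.simulate import ScenarioConfig, simulate_scenario

SMALL_COUNTS = {
    "SoxOct": 120, "MORE": 100, "octamer": 60,
    "MORE_plus1": 40, "Sox_single": 80, "none": 80,
}


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_config():
    return ScenarioConfig(chrom_length=400_000, motif_counts=dict(SMALL_COUNTS))


@pytest.fixture(scope="session")
def small_scenario(small_config):
    """A 480-locus scenario shared across tests (seed fixed)."""
    return simulate_scenario(small_config, seed=7)


@pytest.fixture(scope="session")
def small_genome(small_scenario):
    return {small_scenario.config.chrom_name: small_scenario.sequence}
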
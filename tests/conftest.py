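import numpy as np
import pytest

from regmeth.simulate import SimConfig, simulate_genome, simulate_methylation


@pytest.fixture(scope="session")
def null_dataset():
    """A small no-effect dataset shared across tests that only read it."""
    cfg = SimConfig(affected_scope="none", seed=42)
    genome, truth = simulate_genome(cfg)
    experiment = simulate_methylation(truth, cfg)
    return cfg, genome, truth, experiment


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
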
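import numpy as np
import pytest

from kansformer_epi import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_sim():
    """Small synthetic study shared across tests (seeded, generated once)."""
    cfg = SimConfig.tiny(seed=7)
    tracks, catalog, pairs, truth = simulate_dataset(cfg)
    return {"cfg": cfg, "tracks": tracks, "catalog": catalog,
            "pairs": pairs, "truth": truth}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
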
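import numpy as np
import pytest

from milatoms import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A quick synthetic ERD dataset: fewer trials/sources, same structure."""
    cfg = SyntheticConfig(n_trials_per_class=20, n_background_sources=4,
                          noise_snr_db=20.0, seed=42)
    trials, truth = generate_dataset(cfg)
    return cfg, trials, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
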
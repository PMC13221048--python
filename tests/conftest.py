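import numpy as np
import pytest

from olfosc.synthdata import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_null_dataset():
    """Six participants x 40 trials of pure 1/f background (no effects)."""
    cfg = SimConfig(
        n_participants=6, n_trials=40, fs=128.0, epoch=(-0.5, 2.5), seed=101
    )
    trial_sets, behav = generate_dataset(cfg)
    return cfg, trial_sets, behav


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
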
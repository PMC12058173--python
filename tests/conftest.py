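import numpy as np
import pytest

from wavelet_tf import (
    BurstSpec,
    SyntheticSpec,
    build_bank_range,
    generate,
)


@pytest.fixture(scope="session")
def small_bank():
    """Compact bank for unit tests: 10-40 Hz in 2 Hz steps at 250 Hz."""
    return build_bank_range(10, 40, 2, cycles=7, sampling_rate=250.0)


@pytest.fixture(scope="session")
def tiny_epochs():
    """5 trials x 4 channels with one locked 20 Hz burst at 300 ms, fs=250."""
    spec = SyntheticSpec(
        n_trials=5,
        n_channels=4,
        sampling_rate=250.0,
        epoch_window_ms=(-400.0, 800.0),
        bursts=(BurstSpec(20.0, 300.0, 150.0, 2.0),),
        noise_sd=0.5,
        seed=42,
        condition="tiny",
        subject="01",
    )
    return generate(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
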
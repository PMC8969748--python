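import numpy as np
import pytest

from hafit.audiograms import AUDIOMETRIC_FREQS_KHZ, Audiogram
from hafit.ha_sim import HAConfig, TimeConstants


@pytest.fixture(scope="session")
def zero_loss_audiogram() -> Audiogram:
    return Audiogram(AUDIOMETRIC_FREQS_KHZ, (0.0,) * len(AUDIOMETRIC_FREQS_KHZ))


@pytest.fixture(scope="session")
def flat_audiogram_40() -> Audiogram:
    return Audiogram(AUDIOMETRIC_FREQS_KHZ, (40.0,) * len(AUDIOMETRIC_FREQS_KHZ))


@pytest.fixture
def linear_ha_config() -> HAConfig:
    """CR = 1 in every channel, 0 dB gain, limiter disabled: identity settings."""
    return HAConfig(
        ig65_db=(0.0,) * 5,
        ig85_db=(0.0,) * 5,
        ct_db_spl=(45.0,) * 5,
        limiter_threshold_db_spl=float("inf"),
    )


@pytest.fixture
def compressive_ha_config() -> HAConfig:
    return HAConfig(
        ig65_db=(10.0, 15.0, 20.0, 25.0, 25.0),
        ig85_db=(5.0, 8.0, 12.0, 15.0, 15.0),
        ct_db_spl=(45.0,) * 5,
        limiter_threshold_db_spl=float("inf"),
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
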
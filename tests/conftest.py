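import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from airseq import SyntheticConfig, generate_station  # noqa: E402


@pytest.fixture(scope="session")
def clean_config():
    """Deterministic world: no noise, no meteorology coupling, no gaps."""
    return SyntheticConfig(
        n_days=35, noise_sd=0.0, meteo_coupling={}, missing_rate=0.0, seed=1
    )


@pytest.fixture(scope="session")
def clean_series(clean_config):
    return generate_station(clean_config)


@pytest.fixture(scope="session")
def noisy_config():
    """Default-structure world with gaps, small enough for fast tests."""
    return SyntheticConfig(n_days=40, missing_rate=0.01, seed=7)


@pytest.fixture(scope="session")
def noisy_series(noisy_config):
    return generate_station(noisy_config)
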
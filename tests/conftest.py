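import numpy as np
import pytest

from hypnoval import DeviceErrorModel, Hypnogram, SimScenario


@pytest.fixture
def toy_psg():
    """7-epoch PSG night: wake, sleep block with an awakening, wake tail."""
    return Hypnogram(
        stages=("Wake", "N1", "N2", "Wake", "N2", "Wake", "Wake"),
        epoch_duration=30.0,
        start_time=None,
        source="PSG",
        alphabet="PSG5",
    )


@pytest.fixture
def timed_psg():
    return Hypnogram(
        stages=("Wake", "N1", "N2", "Wake", "N2", "Wake", "Wake"),
        epoch_duration=30.0,
        start_time=__import__("hypnoval").hypnogram.parse_clock_time("23:00:00")[0],
        source="PSG",
        alphabet="PSG5",
    )


@pytest.fixture
def default_scenario():
    return SimScenario(seed=123)


@pytest.fixture
def noisy_scenario():
    return SimScenario(
        seed=123,
        error_model=DeviceErrorModel.uniform_mislabel(0.2, 3),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
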
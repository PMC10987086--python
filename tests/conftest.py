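import numpy as np
import pandas as pd
import pytest

from numchan import ChannelModelConfig, WfMatrix


@pytest.fixture
def flat_config() -> ChannelModelConfig:
    """Untuned 1-channel model at the calibrated study conditions."""
    return ChannelModelConfig.flat()


@pytest.fixture
def two_channel_config() -> ChannelModelConfig:
    """Two channels at 8 and 32, full bandwidth 1.45 octaves."""
    return ChannelModelConfig.two_channel()


@pytest.fixture
def low_noise_two_channel() -> ChannelModelConfig:
    return ChannelModelConfig.two_channel(noise_sd=0.03)


@pytest.fixture
def well_separated_two_channel() -> ChannelModelConfig:
    """Two channels interior to the probed range, narrow tuning, low noise:
    the configuration under which channel parameters are identifiable from
    loading profiles."""
    return ChannelModelConfig(n_channels=2, peaks=(10.0, 26.0),
                              fwhm_octaves=1.0, noise_sd=0.03)


@pytest.fixture
def small_wfm() -> WfMatrix:
    """A hand-sized 5 participants x 4 targets Wf matrix."""
    rng = np.random.default_rng(42)
    return WfMatrix(
        participants=[f"S{i}" for i in range(1, 6)],
        targets=np.array([8.0, 11.0, 16.0, 32.0]),
        values=0.15 + 0.1 * rng.random((5, 4)),
        condition="fast",
    )


def make_trials(responses_by_cell: dict, condition: str = "fast",
                rate: float = 6.8) -> pd.DataFrame:
    """Long trial table from {(participant, target): [responses]}."""
    rows = []
    for (pid, target), responses in responses_by_cell.items():
        for r in responses:
            rows.append((pid, condition, float(target), int(round(r)),
                         float(r) / rate))
    return pd.DataFrame(rows, columns=["participant_id", "condition", "target",
                                       "response_count", "response_duration"])


@pytest.fixture
def trials_factory():
    return make_trials
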
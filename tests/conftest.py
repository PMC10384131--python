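import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from ercpipe import SynthConfig, generate_session

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from ercpipe.containers import EventSchedule, Recording
from ercpipe.montage import CHANNEL_ORDER


def small_synth_config(**overrides) -> SynthConfig:
    """A 5-minute session with tighter cue spacing, for quick tests."""
    defaults = dict(
        duration=300.0,
        mean_interval=40.0,
        sd_interval=10.0,
        min_interval=15.0,
        seed=7,
    )
    defaults.update(overrides)
    return dataclasses.replace(SynthConfig(), **defaults)


@pytest.fixture(scope="session")
def small_session():
    """One reduced synthetic session shared across read-only tests."""
    config = small_synth_config()
    recording, schedule, truth = generate_session(config)
    return config, recording, schedule, truth


@pytest.fixture()
def white_recording():
    """White-noise 14-channel recording, 180 s at 128 Hz."""
    rng = np.random.default_rng(42)
    fs = 128.0
    data = rng.standard_normal((14, int(180 * fs))) * 10.0
    return Recording(data=data, fs=fs, channel_labels=list(CHANNEL_ORDER))


@pytest.fixture()
def even_schedule():
    """20 events, evenly spaced with non-overlapping windows."""
    cues = 10.0 + 8.0 * np.arange(20)
    rng = np.random.default_rng(3)
    rts = np.clip(rng.normal(1.2, 0.3, size=20), 0.3, None)
    return EventSchedule(cue_times=cues, reaction_times=rts)
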
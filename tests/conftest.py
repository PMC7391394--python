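from __future__ import annotations

import numpy as np
import pytest

from vrbreath import BreathSimParams, TrackerConfig, simulate_pose_stream, track


def make_breath_frames(statuses, dt=1.0 / 90.0, t0=0.0):
    """Build a BreathFrames container from a list of status strings."""
    from vrbreath import BreathFrames

    n = len(statuses)
    t = t0 + dt * np.arange(n)
    zeros = np.zeros(n)
    return BreathFrames(t=t, summed_delta=zeros, trend=zeros.copy(), status=np.array(statuses, dtype="U11"))


@pytest.fixture(scope="session")
def cfg():
    return TrackerConfig()


@pytest.fixture(scope="session")
def sine_stream():
    """Clean 0.1 Hz sinusoidal breathing, 120 s at 90 Hz, no jitter."""
    return simulate_pose_stream(
        BreathSimParams(f_breath=0.1, amplitude=0.01, duration=120.0, jitter_sd=0.0, seed=1)
    )


@pytest.fixture(scope="session")
def sine_frames(sine_stream, cfg):
    return track(sine_stream, cfg)
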
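"""Synthetic controller-pose streams and RR series.

No public dataset of belt-mounted VR-controller breathing recordings
exists, so every stage of the pipeline is exercised against simulated
data with the statistical structure the algorithm assumes:

* a pose stream in which abdominal breathing displaces the controller
  sinusoidally (or with asymmetric inhale/exhale fractions and
  breath-holds) along a body-relative axis, with per-axis Gaussian
  tracking jitter and optional injected movement/rotation artifacts;
* an interbeat-interval series with sinusoidal respiratory sinus
  arrhythmia modulation at a configurable breathing frequency, Gaussian
  beat noise, and optional implausible-interval outliers to exercise
  cleaning.

RSA is modelled as pure sinusoidal IBI modulation — enough to place
spectral power in the intended band, which is what the HRV stage
measures; it is not an integral-pulse-frequency cardiac model.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.signal import sawtooth
from scipy.spatial.transform import Rotation

from .hrv import RRSeries
from .tracker import PoseStream

__all__ = [
    "ArtifactEvent",
    "BreathSimParams",
    "RRSimParams",
    "simulate_pose_stream",
    "simulate_rr",
]

# wobble frequencies of injected artifacts; sawtooth (constant-slope)
# waveforms keep the per-frame delta above threshold over the whole span
_F_LATERAL = 11.0  # Hz
_F_ROTATION = 7.0  # Hz

_OUTLIER_LOW = (100.0, 340.0)  # ms, below the 350 ms cleaning bound
_OUTLIER_HIGH = (1850.0, 2500.0)  # ms, above the 1800 ms bound


class ArtifactEvent(BaseModel):
    """A span of controller motion unrelated to breathing.

    During ``[t_start, t_stop)`` a lateral (off-axis) sawtooth
    displacement of amplitude ``lateral_amplitude`` (m) and a yaw wobble
    of amplitude ``rotation_amplitude`` (deg) are added to the pose.
    """

    t_start: float = Field(ge=0.0)
    t_stop: float = Field(gt=0.0)
    lateral_amplitude: float = Field(default=0.01, ge=0.0)
    rotation_amplitude: float = Field(default=10.0, ge=0.0)

    @model_validator(mode="after")
    def _check(self) -> "ArtifactEvent":
        if self.t_stop <= self.t_start:
            raise ValueError("t_stop must be > t_start")
        return self


class BreathSimParams(BaseModel):
    """Parameters of the simulated breathing exercise.

    Defaults mirror a typical study session: a 7-minute (420 s) exercise
    at a 90 Hz tracking rate, ~1 cm abdominal excursion, and 0.3 mm
    per-axis tracking jitter (the RMS positional noise reported for
    consumer outside-in VR tracking).  ``waveform='asymmetric'`` realises unequal
    inhale/exhale durations via ``inhale_fraction``; ``hold_fraction``
    inserts motionless holds at the turning points of each cycle.
    """

    f_breath: float = Field(default=0.1, gt=0.0)
    amplitude: float = Field(default=0.01, gt=0.0)
    duration: float = Field(default=420.0, gt=0.0)
    frame_rate: float = Field(default=90.0, gt=0.0)
    jitter_sd: float = Field(default=0.0003, ge=0.0)
    artifact_events: list[ArtifactEvent] = Field(default_factory=list)
    waveform: str = "sinusoid"
    inhale_fraction: float = Field(default=0.45, gt=0.0, lt=1.0)
    hold_fraction: float = Field(default=0.0, ge=0.0, le=0.9)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "BreathSimParams":
        if self.f_breath >= self.frame_rate / 2:
            raise ValueError("f_breath must be below the Nyquist rate")
        if self.waveform not in ("sinusoid", "asymmetric"):
            raise ValueError("waveform must be 'sinusoid' or 'asymmetric'")
        return self


class RRSimParams(BaseModel):
    """Parameters of the simulated interbeat series.

    ``baseline_rr`` 900 ms (~67 bpm resting heart rate) with 50 ms RSA
    modulation and 5 ms beat noise are typical resting values for a
    healthy adult.
    """

    baseline_rr: float = Field(default=900.0, gt=0.0)
    rsa_amplitude: float = Field(default=50.0, ge=0.0)
    f_breath: float = Field(default=0.1, gt=0.0)
    duration: float = Field(default=300.0, gt=0.0)
    noise_sd: float = Field(default=5.0, ge=0.0)
    outlier_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "RRSimParams":
        if self.baseline_rr - self.rsa_amplitude - 4.0 * self.noise_sd <= 0:
            raise ValueError("baseline_rr - rsa_amplitude - 4*noise_sd must stay positive")
        return self


def _cycle_displacement(u: np.ndarray, amplitude: float, inhale_fraction: float, hold_fraction: float) -> np.ndarray:
    """Displacement over one breath cycle as a function of phase u in [0, 1).

    Piecewise raised-cosine rise (inhale) and fall (exhale) with
    optional holds at full inhalation and full exhalation; velocity is
    zero at every junction, so holds join smoothly.  With equal
    fractions and no hold this reduces to -A*cos(2*pi*u) exactly.
    """
    rise = inhale_fraction * (1.0 - hold_fraction)
    fall = (1.0 - inhale_fraction) * (1.0 - hold_fraction)
    h = hold_fraction / 2.0
    c1 = rise  # end of inhale
    c2 = rise + h  # end of top hold
    c3 = rise + h + fall  # end of exhale
    d = np.empty_like(u)
    m = u < c1
    d[m] = -amplitude * np.cos(np.pi * u[m] / rise)
    m = (u >= c1) & (u < c2)
    d[m] = amplitude
    m = (u >= c2) & (u < c3)
    d[m] = amplitude * np.cos(np.pi * (u[m] - c2) / fall)
    d[u >= c3] = -amplitude
    return d


def simulate_pose_stream(params: BreathSimParams) -> PoseStream:
    """Generate a belt-mounted-controller pose stream.

    The controller rests at the origin with identity orientation, so the
    breathing axis is the world +Z axis (the default controller-local
    axis).  Breathing displaces it along +Z, tracking jitter is i.i.d.
    Gaussian per axis and frame, and each artifact event adds a lateral
    +X sawtooth displacement plus a yaw wobble.  Bit-reproducible for a
    fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.frame_rate))
    if n < 2:
        raise ValueError("duration too short for the given frame rate")
    t = np.arange(n) / params.frame_rate

    u = np.mod(params.f_breath * t, 1.0)
    inhale_fraction = 0.5 if params.waveform == "sinusoid" else params.inhale_fraction
    d = _cycle_displacement(u, params.amplitude, inhale_fraction, params.hold_fraction)

    position = np.zeros((n, 3))
    position[:, 2] = d
    if params.jitter_sd > 0:
        position += rng.normal(0.0, params.jitter_sd, size=(n, 3))

    yaw = np.zeros(n)
    for ev in params.artifact_events:
        m = (t >= ev.t_start) & (t < ev.t_stop)
        if not np.any(m):
            continue
        tau = t[m] - ev.t_start
        position[m, 0] += ev.lateral_amplitude * sawtooth(2.0 * np.pi * _F_LATERAL * tau, width=0.5)
        yaw[m] += ev.rotation_amplitude * sawtooth(2.0 * np.pi * _F_ROTATION * tau, width=0.5)

    if np.any(yaw != 0.0):
        quat = Rotation.from_euler("y", yaw[:, None], degrees=True).as_quat(scalar_first=True)
    else:
        quat = np.tile([1.0, 0.0, 0.0, 0.0], (n, 1))
    return PoseStream(t=t, position=position, orientation=quat)


def simulate_rr(params: RRSimParams) -> RRSeries:
    """Generate a beat-by-beat RR series with sinusoidal RSA.

    Each interval is ``baseline + rsa_amplitude*sin(2*pi*f_breath*t)``
    plus Gaussian noise, evaluated at the current beat time; with
    probability ``outlier_rate`` the interval is instead drawn uniformly
    from an implausible range (100–340 ms or 1850–2500 ms, equally
    likely) to exercise the cleaning stage.  Time advances by the
    recorded interval, outlier or not.
    """
    rng = np.random.default_rng(params.seed)
    intervals: list[float] = []
    t_beat = 0.0
    while t_beat < params.duration:
        ibi = params.baseline_rr + params.rsa_amplitude * np.sin(2.0 * np.pi * params.f_breath * t_beat)
        if params.noise_sd > 0:
            ibi += rng.normal(0.0, params.noise_sd)
        if params.outlier_rate > 0 and rng.random() < params.outlier_rate:
            lo, hi = _OUTLIER_LOW if rng.random() < 0.5 else _OUTLIER_HIGH
            ibi = rng.uniform(lo, hi)
        intervals.append(float(ibi))
        t_beat += ibi / 1000.0
    if len(intervals) < 2:
        raise ValueError("duration too short to produce an RR series")
    return RRSeries(np.array(intervals))
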
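"""Breath-state tracking from 6-DOF controller pose streams.

A VR hand controller strapped to the abdomen moves forward during
inhalation (abdominal expansion) and backward during exhalation
(contraction).  The tracker turns a raw pose stream into a per-frame
respiratory status in four steps:

1. *Calibration* — fix the **target vector**, the world-frame axis
   orthogonal to the abdominal wall, by averaging the rotated
   controller-local axis over an initial window of frames.
2. *Projection* — per frame, decompose the positional delta into its
   component along the target vector (breathing motion), the orthogonal
   remainder (unrelated motion), and the rotational delta.
3. *Trend* — accumulate the target-axis deltas into a summed-delta
   series and take short-MA minus long-MA of it; the sign of this trend
   classifies inhalation (positive) vs exhalation (negative), with a
   small dead zone around zero for tracking noise.
4. *Artifact gating* — frames whose off-axis or rotational delta exceeds
   a threshold are labelled movement artifacts regardless of trend,
   since diaphragmatic breathing cannot explain such motion.

All positions are in meters, times in seconds, angles in degrees.
Quaternions are scalar-first ``(w, x, y, z)``; the world frame is
right-handed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from pydantic import BaseModel, Field, model_validator
from scipy.spatial.transform import Rotation

__all__ = [
    "INHALATION",
    "EXHALATION",
    "NO_MOVEMENT",
    "ARTIFACT",
    "STATUSES",
    "CalibrationError",
    "PoseSample",
    "PoseStream",
    "TrackerConfig",
    "FrameDelta",
    "BreathFrame",
    "BreathFrames",
    "calibrate_target_vector",
    "frame_delta",
    "accumulate_and_trend",
    "classify_frame",
    "track",
]

INHALATION = "inhalation"
EXHALATION = "exhalation"
NO_MOVEMENT = "no_movement"
ARTIFACT = "artifact"
#: The four mutually exclusive respiratory statuses.
STATUSES = (INHALATION, EXHALATION, NO_MOVEMENT, ARTIFACT)

_LOCAL_AXES = {
    "+x": np.array([1.0, 0.0, 0.0]),
    "-x": np.array([-1.0, 0.0, 0.0]),
    "+y": np.array([0.0, 1.0, 0.0]),
    "-y": np.array([0.0, -1.0, 0.0]),
    "+z": np.array([0.0, 0.0, 1.0]),
    "-z": np.array([0.0, 0.0, -1.0]),
}

_QUAT_NORM_TOL = 1e-6


class CalibrationError(ValueError):
    """Raised when the target vector cannot be derived from a stream."""


class PoseSample(NamedTuple):
    """One timestamped 6-DOF controller pose.

    Attributes
    ----------
    t : float
        Seconds since stream start; strictly increasing within a stream.
    position : ndarray, shape (3,)
        World-frame position in meters (right-handed frame).
    orientation : ndarray, shape (4,)
        Unit quaternion, scalar-first ``(w, x, y, z)``.
    """

    t: float
    position: np.ndarray
    orientation: np.ndarray


@dataclass(frozen=True)
class PoseStream:
    """A pose time series stored as contiguous arrays.

    Column-wise storage keeps per-frame operations vectorisable; a
    nominal consumer-VR stream runs at ~90 Hz (frame spacing 11–14 ms),
    so a 7-minute exercise is ~38k frames.
    """

    t: np.ndarray
    position: np.ndarray
    orientation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "orientation", np.asarray(self.orientation, dtype=float))

    def __len__(self) -> int:
        return self.t.shape[0]

    def __getitem__(self, i: int) -> PoseSample:
        return PoseSample(float(self.t[i]), self.position[i], self.orientation[i])

    def __iter__(self) -> Iterator[PoseSample]:
        for i in range(len(self)):
            yield self[i]

    @classmethod
    def from_samples(cls, samples: Iterable[PoseSample]) -> "PoseStream":
        samples = list(samples)
        return cls(
            t=np.array([s.t for s in samples], dtype=float),
            position=np.array([s.position for s in samples], dtype=float),
            orientation=np.array([s.orientation for s in samples], dtype=float),
        )

    def validate(self) -> "PoseStream":
        """Check stream invariants; raise ``ValueError`` naming the first bad frame."""
        if self.t.ndim != 1 or self.position.shape != (len(self), 3) or self.orientation.shape != (len(self), 4):
            raise ValueError("pose stream arrays have inconsistent shapes")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.position)) or not np.all(
            np.isfinite(self.orientation)
        ):
            bad = int(
                np.flatnonzero(
                    ~(
                        np.isfinite(self.t)
                        & np.isfinite(self.position).all(axis=1)
                        & np.isfinite(self.orientation).all(axis=1)
                    )
                )[0]
            )
            raise ValueError(f"non-finite pose values at frame {bad}")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            bad = int(np.flatnonzero(dt <= 0)[0]) + 1
            raise ValueError(f"timestamps not strictly increasing at frame {bad}")
        norms = np.linalg.norm(self.orientation, axis=1)
        if np.any(np.abs(norms - 1.0) > _QUAT_NORM_TOL):
            bad = int(np.flatnonzero(np.abs(norms - 1.0) > _QUAT_NORM_TOL)[0])
            raise ValueError(f"orientation quaternion not unit-norm at frame {bad}")
        return self


class TrackerConfig(BaseModel):
    """Windows and thresholds of the breath-state classifier.

    ``w_short``/``w_long`` are moving-average lengths counted in frames
    (10 and 90 by default, i.e. ~0.11 s and ~1 s at 90 Hz).
    ``noise_threshold`` is the dead zone around zero trend below which a
    frame counts as no movement.  ``nontarget_threshold`` (m/frame) and
    ``rotation_threshold`` (deg/frame) gate movement artifacts.
    """

    w_short: int = Field(default=10, ge=1)
    w_long: int = Field(default=90, ge=2)
    noise_threshold: float = Field(default=2e-4, ge=0.0)
    nontarget_threshold: float = Field(default=2e-3, ge=0.0)
    rotation_threshold: float = Field(default=0.5, ge=0.0)
    calibration_frames: int = Field(default=90, ge=1)
    local_axis: str = "+z"

    @model_validator(mode="after")
    def _check(self) -> "TrackerConfig":
        if self.w_short >= self.w_long:
            raise ValueError("w_short must be < w_long")
        if self.local_axis not in _LOCAL_AXES:
            raise ValueError(f"local_axis must be one of {sorted(_LOCAL_AXES)}")
        return self

    @property
    def local_axis_vector(self) -> np.ndarray:
        return _LOCAL_AXES[self.local_axis].copy()


class FrameDelta(NamedTuple):
    """Per-frame motion decomposition relative to the previous frame.

    ``target_delta`` is the signed displacement (m) along the target
    vector; ``nontarget_delta`` the magnitude (m) of the orthogonal
    remainder; ``rotation_delta`` the relative rotation angle (deg,
    in [0, 180]).
    """

    target_delta: float
    nontarget_delta: float
    rotation_delta: float


class BreathFrame(NamedTuple):
    """One classified frame: time, summed delta, trend, status."""

    t: float
    summed_delta: float
    trend: float
    status: str


@dataclass(frozen=True)
class BreathFrames:
    """Classified output of :func:`track`, one row per post-calibration frame."""

    t: np.ndarray
    summed_delta: np.ndarray
    trend: np.ndarray
    status: np.ndarray

    def __len__(self) -> int:
        return self.t.shape[0]

    def __getitem__(self, i: int) -> BreathFrame:
        return BreathFrame(
            float(self.t[i]), float(self.summed_delta[i]), float(self.trend[i]), str(self.status[i])
        )

    def __iter__(self) -> Iterator[BreathFrame]:
        for i in range(len(self)):
            yield self[i]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.t, "summed_delta": self.summed_delta, "trend": self.trend, "status": self.status}
        )

    def status_counts(self) -> dict:
        return {s: int(np.sum(self.status == s)) for s in STATUSES}


def _rotations(quats_wxyz: np.ndarray) -> Rotation:
    return Rotation.from_quat(np.atleast_2d(quats_wxyz), scalar_first=True)


def calibrate_target_vector(stream: PoseStream | Sequence[PoseSample], cfg: TrackerConfig) -> np.ndarray:
    """Fix the breathing axis from the first ``calibration_frames`` frames.

    The controller-local axis (``cfg.local_axis``, +Z by default) is
    rotated into the world frame by each calibration orientation; the
    mean of those world axes, renormalised, is the target vector.  It is
    held fixed afterwards: with a belt-mounted controller the axis is
    static relative to the abdomen, and any later rotation is then a
    pure artifact signal.

    Raises
    ------
    CalibrationError
        If the stream is shorter than ``calibration_frames`` or the mean
        axis is degenerate (near zero, e.g. orientations spread over a
        half sphere).
    """
    if not isinstance(stream, PoseStream):
        stream = PoseStream.from_samples(stream)
    if len(stream) < cfg.calibration_frames:
        raise CalibrationError(
            f"need at least {cfg.calibration_frames} frames to calibrate, got {len(stream)}"
        )
    quats = stream.orientation[: cfg.calibration_frames]
    axes = _rotations(quats).apply(cfg.local_axis_vector)
    mean_axis = axes.mean(axis=0)
    norm = np.linalg.norm(mean_axis)
    if norm < 1e-6:
        raise CalibrationError("degenerate calibration: mean rotated axis is near zero")
    return mean_axis / norm


def frame_delta(prev: PoseSample, curr: PoseSample, target: np.ndarray) -> FrameDelta:
    """Decompose the motion between two consecutive frames.

    Returns the signed target-axis displacement, the magnitude of the
    orthogonal displacement, and the relative rotation angle in degrees.
    """
    if prev.t >= curr.t:
        raise ValueError("frames out of order: prev.t must be < curr.t")
    dp = np.asarray(curr.position, dtype=float) - np.asarray(prev.position, dtype=float)
    if not np.all(np.isfinite(dp)):
        raise ValueError("non-finite positions")
    target = np.asarray(target, dtype=float)
    td = float(dp @ target)
    nd = float(np.linalg.norm(dp - td * target))
    r_prev = _rotations(np.asarray(prev.orientation))
    r_curr = _rotations(np.asarray(curr.orientation))
    rd = float(np.degrees((r_prev.inv() * r_curr).magnitude()[0]))
    return FrameDelta(td, nd, rd)


def _moving_mean(x: np.ndarray, w: int) -> np.ndarray:
    """Causal moving mean with an expanding window during warm-up.

    Each full window is averaged independently (no recursive running
    sum), so the result agrees with a naive per-window recomputation to
    round-off of a single window sum.
    """
    n = x.shape[0]
    out = np.empty(n, dtype=float)
    head = min(w, n)
    out[:head] = np.cumsum(x[:head]) / np.arange(1, head + 1)
    if n >= w:
        out[w - 1 :] = sliding_window_view(x, w).mean(axis=1)
    return out


def accumulate_and_trend(
    deltas: Sequence[FrameDelta] | np.ndarray, cfg: TrackerConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulate target-axis deltas and compute the short-minus-long trend.

    ``summed_delta[k]`` is the running sum of target deltas up to frame
    ``k`` — an estimate of absolute abdominal position along the target
    vector.  ``trend[k]`` is the mean of the last ``w_short`` summed
    values minus the mean of the last ``w_long``, with expanding windows
    while fewer frames are available.  Both are causal: frame ``k`` uses
    only frames ``<= k``.
    """
    deltas = list(deltas) if not isinstance(deltas, np.ndarray) else deltas
    if len(deltas) == 0:
        raise ValueError("empty delta sequence")
    if isinstance(deltas, np.ndarray) and deltas.ndim == 1:
        target = np.asarray(deltas, dtype=float)
    elif isinstance(deltas[0], FrameDelta):
        target = np.array([d.target_delta for d in deltas], dtype=float)
    else:
        target = np.asarray(deltas, dtype=float)
    summed = np.cumsum(target)
    trend = _moving_mean(summed, cfg.w_short) - _moving_mean(summed, cfg.w_long)
    return summed, trend


def _classify_arrays(
    trend: np.ndarray, nontarget: np.ndarray, rotation: np.ndarray, cfg: TrackerConfig
) -> np.ndarray:
    status = np.full(trend.shape[0], NO_MOVEMENT, dtype="U11")
    status[trend > cfg.noise_threshold] = INHALATION
    status[trend < -cfg.noise_threshold] = EXHALATION
    # artifact wins: off-axis or rotational motion means breathing cannot
    # explain the frame, whatever the trend says
    status[(nontarget > cfg.nontarget_threshold) | (rotation > cfg.rotation_threshold)] = ARTIFACT
    return status


def classify_frame(trend: float, delta: FrameDelta, cfg: TrackerConfig) -> str:
    """Classify one frame from its trend value and motion decomposition.

    Artifact takes priority; otherwise the sign of the trend against the
    noise dead zone decides inhalation / exhalation / no movement.
    """
    if delta.nontarget_delta > cfg.nontarget_threshold or delta.rotation_delta > cfg.rotation_threshold:
        return ARTIFACT
    if trend > cfg.noise_threshold:
        return INHALATION
    if trend < -cfg.noise_threshold:
        return EXHALATION
    return NO_MOVEMENT


def stream_deltas(stream: PoseStream, target: np.ndarray, start: int = 1) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-frame deltas for frames ``start..n-1`` (each vs its predecessor)."""
    dp = stream.position[start:] - stream.position[start - 1 : -1]
    td = dp @ target
    nd = np.linalg.norm(dp - np.outer(td, target), axis=1)
    rots = _rotations(stream.orientation)
    rd = np.degrees((rots[start - 1 : -1].inv() * rots[start:]).magnitude())
    return td, nd, rd


def track(stream: PoseStream | Sequence[PoseSample], cfg: TrackerConfig | None = None) -> BreathFrames:
    """Run the full pipeline: calibrate, project, accumulate, classify.

    Emits one :class:`BreathFrame` per post-calibration frame (index
    ``>= cfg.calibration_frames``); each frame's delta is taken against
    its immediate predecessor, so the summed-delta series starts at the
    end of the calibration window.  Deterministic for fixed input and
    config.
    """
    cfg = cfg or TrackerConfig()
    if not isinstance(stream, PoseStream):
        stream = PoseStream.from_samples(stream)
    stream.validate()
    target = calibrate_target_vector(stream, cfg)
    cal = cfg.calibration_frames
    if len(stream) <= cal:
        empty = np.empty(0)
        return BreathFrames(empty, empty.copy(), empty.copy(), np.empty(0, dtype="U11"))
    td, nd, rd = stream_deltas(stream, target, start=cal)
    summed, trend = accumulate_and_trend(td, cfg)
    status = _classify_arrays(trend, nd, rd, cfg)
    return BreathFrames(t=stream.t[cal:].copy(), summed_delta=summed, trend=trend, status=status)
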
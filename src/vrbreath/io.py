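"""Readers and writers for the package's plain-text formats.

* pose stream CSV (header ``t,px,py,pz,qw,qx,qy,qz``, SI units) and an
  equivalent JSONL variant with the same field names;
* breath-frame CSV (``t,summed_delta,trend,status``);
* segment CSV (``status,t_start,t_end,duration``);
* RR series as one interval in milliseconds per line (the common IBI
  text export of chest-strap apps);
* feedback events as JSONL;
* tracker config as a flat key/value (YAML) file.

Readers validate and report the first offending file line by number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .feedback import FeedbackEvent
from .hrv import RRSeries
from .metrics import BreathSegment
from .tracker import STATUSES, BreathFrames, PoseStream, TrackerConfig

__all__ = [
    "read_pose_csv",
    "write_pose_csv",
    "read_pose_jsonl",
    "write_pose_jsonl",
    "read_pose",
    "read_breath_frames_csv",
    "write_breath_frames_csv",
    "write_segments_csv",
    "read_rr_text",
    "write_rr_text",
    "write_events_jsonl",
    "read_events_jsonl",
    "load_tracker_config",
    "write_tracker_config",
    "write_json",
]

_POSE_COLUMNS = ["t", "px", "py", "pz", "qw", "qx", "qy", "qz"]


def _pose_from_frame(df: pd.DataFrame, path: str | Path) -> PoseStream:
    missing = [c for c in _POSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    values = df[_POSE_COLUMNS].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(values).all(axis=1))
    if bad.size:
        # +2: one for the header, one for 1-based numbering
        raise ValueError(f"{path}: malformed pose row at line {int(bad[0]) + 2}")
    return PoseStream(t=values[:, 0], position=values[:, 1:4], orientation=values[:, 4:8]).validate()


def read_pose_csv(path: str | Path) -> PoseStream:
    df = pd.read_csv(path, dtype=str, comment="#")
    return _pose_from_frame(df, path)


def write_pose_csv(stream: PoseStream, path: str | Path) -> None:
    df = pd.DataFrame(
        np.column_stack([stream.t, stream.position, stream.orientation]), columns=_POSE_COLUMNS
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_pose_jsonl(path: str | Path) -> PoseStream:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                rows.append([float(rec[c]) for c in _POSE_COLUMNS])
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}: malformed pose record at line {lineno}") from exc
    arr = np.asarray(rows, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{path}: no pose records")
    return PoseStream(t=arr[:, 0], position=arr[:, 1:4], orientation=arr[:, 4:8]).validate()


def write_pose_jsonl(stream: PoseStream, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in stream:
            rec = {
                "t": s.t,
                "px": s.position[0],
                "py": s.position[1],
                "pz": s.position[2],
                "qw": s.orientation[0],
                "qx": s.orientation[1],
                "qy": s.orientation[2],
                "qz": s.orientation[3],
            }
            fh.write(json.dumps(rec) + "\n")


def read_pose(path: str | Path) -> PoseStream:
    """Dispatch on extension: ``.jsonl``/``.json`` → JSONL, else CSV."""
    if str(path).endswith((".jsonl", ".json")):
        return read_pose_jsonl(path)
    return read_pose_csv(path)


def read_breath_frames_csv(path: str | Path) -> BreathFrames:
    df = pd.read_csv(path)
    needed = ["t", "summed_delta", "trend", "status"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    status = df["status"].to_numpy(dtype="U11")
    unknown = np.flatnonzero(~np.isin(status, STATUSES))
    if unknown.size:
        raise ValueError(f"{path}: unknown status at line {int(unknown[0]) + 2}")
    return BreathFrames(
        t=df["t"].to_numpy(dtype=float),
        summed_delta=df["summed_delta"].to_numpy(dtype=float),
        trend=df["trend"].to_numpy(dtype=float),
        status=status,
    )


def write_breath_frames_csv(frames: BreathFrames, path: str | Path) -> None:
    frames.to_dataframe().to_csv(path, index=False, float_format="%.9g")


def write_segments_csv(segments: Sequence[BreathSegment], path: str | Path) -> None:
    pd.DataFrame(
        {
            "status": [s.status for s in segments],
            "t_start": [s.t_start for s in segments],
            "t_end": [s.t_end for s in segments],
            "duration": [s.duration for s in segments],
        }
    ).to_csv(path, index=False, float_format="%.9g")


def read_rr_text(path: str | Path) -> RRSeries:
    """One interbeat interval in milliseconds per line; blank lines skipped."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                intervals.append(float(line))
            except ValueError as exc:
                raise ValueError(f"{path}: malformed RR value at line {lineno}") from exc
    if not intervals:
        raise ValueError(f"{path}: no RR intervals")
    return RRSeries(np.array(intervals))


def write_rr_text(rr: RRSeries, path: str | Path) -> None:
    with open(path, "w") as fh:
        for v in rr.intervals:
            fh.write(f"{v:.6g}\n")


def write_events_jsonl(events: Sequence[FeedbackEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(json.dumps({"kind": ev.kind, "t": ev.t}) + "\n")


def read_events_jsonl(path: str | Path) -> list[FeedbackEvent]:
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                events.append(FeedbackEvent(kind=str(rec["kind"]), t=float(rec["t"])))
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}: malformed event at line {lineno}") from exc
    return events


def load_tracker_config(path: str | Path) -> TrackerConfig:
    """Flat key/value file mirroring :class:`TrackerConfig` field names."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a flat key/value mapping")
    return TrackerConfig(**data)


def write_tracker_config(cfg: TrackerConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, default_flow_style=False)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
        fh.write("\n")
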
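"""End-to-end report: pose stream (plus optional RR series) → JSON-able dict."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

from . import __version__
from .feedback import feedback_events, total_on_time
from .hrv import HRVConfig, summarize_hrv
from .io import read_pose, read_rr_text
from .metrics import SpectrumConfig, summarize_respiration
from .tracker import TrackerConfig, calibrate_target_vector, track

__all__ = ["run_pipeline"]

log = logging.getLogger("vrbreath")


def _versions() -> dict:
    import numpy
    import pandas
    import scipy

    return {
        "vrbreath": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }


def run_pipeline(
    pose_path: str | Path,
    rr_path: Optional[str | Path] = None,
    tracker_config: TrackerConfig | None = None,
    spectrum_config: SpectrumConfig | None = None,
    hrv_config: HRVConfig | None = None,
) -> dict:
    """Classify a pose stream, summarise respiration (and HRV if RR given).

    Returns a JSON-serialisable report with a tracker block (frame and
    status counts, calibrated target vector), the respiration summary,
    the feedback-event tally, an HRV block when an RR path is supplied,
    and a provenance block (effective configs and library versions).
    Deterministic for fixed inputs and configuration.
    """
    tracker_config = tracker_config or TrackerConfig()
    spectrum_config = spectrum_config or SpectrumConfig()
    hrv_config = hrv_config or HRVConfig()

    stream = read_pose(pose_path)
    log.info("read %d pose frames from %s", len(stream), pose_path)
    target = calibrate_target_vector(stream, tracker_config)
    frames = track(stream, tracker_config)
    resp = summarize_respiration(frames, spectrum_config)
    events = feedback_events(frames)

    report: dict = {
        "tracker": {
            "n_frames": len(stream),
            "n_calibration_frames": tracker_config.calibration_frames,
            "n_classified_frames": len(frames),
            "target_vector": [float(v) for v in target],
            "status_counts": frames.status_counts(),
        },
        "respiration": resp.to_dict(),
        "feedback": {
            "n_events": len(events),
            "total_on_time_s": total_on_time(events),
        },
        "provenance": {
            "pose_path": str(pose_path),
            "rr_path": None if rr_path is None else str(rr_path),
            "tracker_config": tracker_config.model_dump(),
            "spectrum_config": spectrum_config.model_dump(),
            "hrv_config": hrv_config.model_dump(),
            "versions": _versions(),
        },
    }
    if rr_path is not None:
        rr = read_rr_text(rr_path)
        log.info("read %d RR intervals from %s", len(rr), rr_path)
        report["hrv"] = summarize_hrv(rr, hrv_config).to_dict()
    return report
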
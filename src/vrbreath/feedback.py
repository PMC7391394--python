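"""Exhalation-gated feedback events.

In the biofeedback condition, scene elements change colour whenever the
user is exhaling, and the change lasts exactly as long as the
exhalation.  This module reduces a classified breath-frame stream to the
minimal event stream a front-end needs to replay that behaviour: an
``on`` event at each transition into exhalation and an ``off`` event at
each transition out of it.  Artifact frames inside an exhalation end the
feedback, consistent with segment termination in the metrics stage.
No debouncing is applied: a one-frame exhalation flicker produces a
one-frame on/off pair.
"""

from __future__ import annotations

from dataclasses import dataclass

from .metrics import segment_statuses
from .tracker import EXHALATION, BreathFrames

__all__ = ["FeedbackEvent", "feedback_events", "total_on_time"]


@dataclass(frozen=True)
class FeedbackEvent:
    """A feedback state change: ``kind`` is ``"on"`` or ``"off"``."""

    kind: str
    t: float


def feedback_events(frames: BreathFrames) -> list[FeedbackEvent]:
    """Emit alternating on/off events bracketing every exhalation segment.

    Events use the same time convention as the segmenter, so the summed
    on-time equals the total exhalation-segment duration exactly.
    """
    if len(frames) == 0:
        return []
    events: list[FeedbackEvent] = []
    for seg in segment_statuses(frames):
        if seg.status == EXHALATION:
            events.append(FeedbackEvent("on", seg.t_start))
            events.append(FeedbackEvent("off", seg.t_end))
    return events


def total_on_time(events: list[FeedbackEvent]) -> float:
    """Summed on→off duration in seconds."""
    return sum(off.t - on.t for on, off in zip(events[::2], events[1::2]))
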
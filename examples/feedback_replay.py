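"""Turn a classified stream into the exhalation-gated feedback events.

The VR scene changes colour whenever the user exhales, for exactly as
long as the exhalation; the event stream below is all a front-end needs
to replay that.  The summed on-time equals the exhalation time exactly.
"""

from vrbreath import (
    EXHALATION,
    BreathSimParams,
    feedback_events,
    segment_statuses,
    simulate_pose_stream,
    total_on_time,
    track,
)

frames = track(simulate_pose_stream(BreathSimParams(duration=60.0, seed=3)))
events = feedback_events(frames)

print(f"{len(events)} events ({len(events) // 2} exhalations); first five:")
for ev in events[:5]:
    print(f"  {ev.kind:>3} @ {ev.t:7.3f} s")

exh_time = sum(s.duration for s in segment_statuses(frames) if s.status == EXHALATION)
print(f"total on-time {total_on_time(events):.3f} s vs exhalation time {exh_time:.3f} s")
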
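# Methods

## Signal model and assumptions

The tracker assumes a controller fixed to the abdomen by a belt, so that
(i) diaphragmatic breathing displaces it along a single body-relative
axis — forward on inhalation, backward on exhalation — and (ii) any
controller rotation, or translation off that axis, is motion the
breathing model cannot explain. Both assumptions are what make the
four-step algorithm identifiable: breathing lives entirely in the
target-axis projection, everything else is an artifact signal.

**Target vector.** The breathing axis is estimated once, at the start of
a stream, as the renormalised mean over `calibration_frames` (default
90, ≈1 s at 90 Hz) of the controller-local axis (`local_axis`, default
+Z) rotated into the world frame, and then frozen. Freezing is a
deliberate choice: with a belt-mounted controller the axis is static
relative to the abdomen, and a frozen axis makes any later rotation a
clean artifact signal. Re-deriving the axis per frame (e.g. to follow a
user turning around) is explicitly out of scope; streams in which the
user reorients mid-exercise will show the turn as artifact frames, which
is the intended behaviour.

**Trend operator.** The summed-delta series (cumulative target-axis
displacement) is compared through `trend = shortMA − longMA`. With this
orientation the trend's sign directly encodes the classification:
positive = the abdomen is currently further out than its recent
baseline = inhalation. Both moving averages are *causal* (frame *k* uses
only frames ≤ *k*), because the live system must classify in real time;
during warm-up the windows expand from length 1 until they reach their
nominal lengths, so output is defined from frame 0. Windows are counted
in frames (10 and 90), not seconds, also under variable frame intervals.

**Classification.** Artifact takes precedence over the trend-based
statuses: when the off-axis or rotational delta exceeds its threshold,
proper diaphragmatic breathing is unlikely in that frame regardless of
what the trend says. Threshold comparisons are strict (`>`), so a value
exactly at a threshold is not flagged; a trend exactly at the dead-zone
edge is `no_movement`.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `w_short` | 10 | frames | smoothing window, ≈0.11 s at 90 Hz |
| `w_long` | 90 | frames | trend baseline, ≈1 s at 90 Hz |
| `noise_threshold` | 2·10⁻⁴ | m | trend dead zone; above residual jitter after the MA difference (≈0.1 mm RMS for 0.3 mm/axis tracking noise), far below breathing trend amplitudes (millimetres) |
| `nontarget_threshold` | 2·10⁻³ | m/frame | off-axis artifact gate; breathing produces essentially no off-axis motion, deliberate arm movement produces much more |
| `rotation_threshold` | 0.5 | °/frame | ≈45 °/s at 90 Hz; breathing does not rotate a belt-mounted controller |
| `calibration_frames` | 90 | frames | ≈1 s; long enough to average orientation jitter |

None of these thresholds is canonical; all are config-exposed (and CLI
flags) precisely so they can be tuned per tracking hardware.

## Respiration metrics

Statuses are run-length encoded into segments. A segment starts at the
time of its first frame and ends at the time of the first frame after
the run; the last segment ends at the last frame time plus the median
frame interval. This convention makes consecutive segments abut exactly
and makes the shares of a uniform stream exact; it needs at least two
frames (a single frame has no defined duration). Segment durations
therefore tile the exercise, and the four relative shares sum to 100%
by construction. An artifact frame inside an inhalation or exhalation
terminates that segment: an artifact-interrupted movement counts as two
movements.

Mean movement durations are plain arithmetic means of the segment
durations per category; a category with no segments yields a flagged
missing value (`None`), never zero.

The respiratory rate is the frequency of the Welch PSD maximum of the
trend series within 0.05–0.5 Hz (3–30 breaths/min). Welch settings —
4096-sample segments (≈45.5 s at 90 Hz), Hann taper, 50% overlap — give
≈0.022 Hz resolution over a 7-minute exercise while averaging several
segments; a shorter series shrinks the segment to the series length.
The series is mean-removed before the transform, which together with
peak-picking makes the estimate exactly invariant to offset and scale.
A constant series (variance below 10⁻²⁴ m², i.e. sub-nanometre) yields
an undefined-rate flag rather than an arbitrary peak. Trend values of
artifact frames are included by default
(`SpectrumConfig.include_artifact_frames=False` drops them); for the
brief artifact spans the classifier tolerates, their spectral leakage is
negligible.

Counting individual breaths is deliberately not attempted: abdominal
movement alone cannot resolve breath boundaries reliably, so the package
reports only the spectral rate.

## HRV

RR cleaning replaces intervals outside 350–1800 ms by linear
interpolation *over index* between the nearest in-bounds neighbours
(edge outliers take the nearest in-bounds value), mirroring common HRV
software; interpolation over beat time would differ only at third-order
for the short gaps involved. Cleaning is idempotent, since interpolants
lie between in-bounds values.

RMSSD is computed directly from successive differences. Band powers are
computed on the tachogram: intervals placed at their beat times,
linearly interpolated onto a uniform 4 Hz grid, mean-removed, Welch PSD
(256-sample segments ≈64 s, Hann, 50% overlap), then trapezoidal
integration of the density over VLF (0.003–0.04 Hz), LF (0.04–0.15 Hz)
and HF (0.15–0.4 Hz). Powers are reported in ms² (integral of density),
so a sinusoidal modulation of amplitude *A* ms carries ≈*A*²/2 ms² into
its band. Published absolute LF/HF magnitudes are software-convention
dependent and are not treated as reproduction targets; only the
between-group F statistics recomputed from printed summaries are.

## Synthetic data

The pose generator emulates: sinusoidal (or asymmetric-fraction)
abdominal displacement of amplitude ~1 cm along the body axis, optional
holds at the turning points, i.i.d. Gaussian tracking jitter of 0.3 mm
per axis per frame (the RMS positional noise reported for consumer
outside-in VR tracking), and injected artifact events. Artifact events
use *sawtooth* (constant-slope) lateral and yaw wobbles rather than
sinusoidal ones: a sinusoid's per-frame delta falls below the artifact
thresholds near its derivative zeros, whereas a constant-slope wobble
keeps the whole injected span above threshold, so the injected artifact
share is recovered to within a couple of percentage points.

The RR generator produces beat-by-beat intervals
`baseline + A·sin(2πf·t_beat) + noise`, with optional implausible-value
outliers to exercise cleaning. RSA is modelled as pure sinusoidal IBI
modulation — sufficient to place power in the intended band, which is
what the HRV stage measures — not as an integral-pulse-frequency cardiac
model; it reproduces neither realistic HRV broadband structure nor
cardiorespiratory phase coupling.

What passing tests therefore show: the pipeline recovers the breathing
frequency, status timing and injected artifact structure of signals that
match its model, and the HRV stage places sinusoidal RSA power in the
correct band. What they do not show: performance on real tracking data
with temporally correlated noise, posture drift, irregular human
breathing or ectopic beats.

## Numerical choices

- Moving averages evaluate each full window independently
  (`sliding_window_view(...).mean`), not via a recursive running sum, so
  they match a literal per-window recomputation to <10⁻¹² m on streams
  of thousands of frames.
- Quaternions are scalar-first `(w,x,y,z)`; rotation deltas are the
  angle of the relative rotation, in [0°, 180°].
- Degenerate calibration (mean rotated axis < 10⁻⁶) and streams shorter
  than the calibration window raise a calibration error rather than
  returning an arbitrary axis.
- The summary ANOVA flags zero pooled variance explicitly: F = 0 for
  equal means, ∞ for unequal means.

## Problem sizes

Tests and the acceptance script use 7-minute (420 s) streams at 90 Hz
(~38k frames) for end-to-end rate recovery — 20 seeded replicates at
each of 0.08, 0.1, 0.15 and 0.25 Hz — and 5-minute RR series (~330
beats) for the HRV band-placement checks; shorter 30–120 s streams
suffice for the structural and conservation tests.

## Known limitations

- The target vector is never re-calibrated; user reorientation appears
  as artifact time.
- No debouncing of one-frame exhalation flickers in the feedback stream
  (matching the segmenter; front-ends wanting hysteresis must add it).
- The respiratory-rate estimate is a spectral approximation, not a
  breath count, and is undefined for motionless streams.
- The generators make no claim of physiological realism beyond band
  placement and share structure.
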
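"""Breath tracker: calibration, motion decomposition, trend, classification."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from vrbreath import (
    ARTIFACT,
    EXHALATION,
    INHALATION,
    NO_MOVEMENT,
    ArtifactEvent,
    BreathSimParams,
    CalibrationError,
    FrameDelta,
    PoseSample,
    PoseStream,
    TrackerConfig,
    accumulate_and_trend,
    calibrate_target_vector,
    classify_frame,
    frame_delta,
    simulate_pose_stream,
    track,
)

from _oracles import naive_accumulate_and_trend

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def still_stream(n, quat=IDENTITY, dt=1 / 90):
    t = dt * np.arange(n)
    return PoseStream(t=t, position=np.zeros((n, 3)), orientation=np.tile(quat, (n, 1)))


class TestCalibration:
    def test_identity_orientations_give_local_axis(self, cfg):
        target = calibrate_target_vector(still_stream(90), cfg)
        assert np.allclose(target, [0, 0, 1])

    def test_yaw90_rotates_z_axis_to_x(self, cfg):
        # 90 deg about world Y maps controller-local +Z to world +X
        q = np.array([np.cos(np.pi / 4), 0.0, np.sin(np.pi / 4), 0.0])
        target = calibrate_target_vector(still_stream(90, quat=q), cfg)
        assert np.allclose(target, [1, 0, 0], atol=1e-9)

    def test_symmetric_yaw_wobble_averages_out(self, cfg):
        # alternating +-10 deg yaw: the rotated axes are mirror images, the
        # renormalised mean is the unperturbed +Z axis
        qp = Rotation.from_euler("y", 10, degrees=True).as_quat(scalar_first=True)
        qm = Rotation.from_euler("y", -10, degrees=True).as_quat(scalar_first=True)
        quats = np.tile(np.stack([qp, qm]), (45, 1))
        stream = PoseStream(t=np.arange(90) / 90, position=np.zeros((90, 3)), orientation=quats)
        target = calibrate_target_vector(stream, cfg)
        assert np.allclose(target, [0, 0, 1], atol=1e-12)

    def test_too_short_stream_raises(self, cfg):
        with pytest.raises(CalibrationError):
            calibrate_target_vector(still_stream(89), cfg)

    def test_degenerate_mean_axis_raises(self, cfg):
        # half the frames flip +Z to -Z (180 deg about X): mean axis ~ 0
        q_flip = np.array([0.0, 1.0, 0.0, 0.0])
        quats = np.tile(np.stack([IDENTITY, q_flip]), (45, 1))
        stream = PoseStream(t=np.arange(90) / 90, position=np.zeros((90, 3)), orientation=quats)
        with pytest.raises(CalibrationError):
            calibrate_target_vector(stream, cfg)


class TestFrameDelta:
    TARGET = np.array([1.0, 0.0, 0.0])

    @pytest.mark.parametrize(
        "displacement, expected_target, expected_nontarget",
        [
            ([0.001, 0.0, 0.0], 0.001, 0.0),  # pure target-axis motion
            ([0.0, 0.001, 0.0], 0.0, 0.001),  # pure off-axis motion
            ([0.003, 0.004, 0.0], 0.003, 0.004),  # 3-4-5 decomposition
            ([-0.002, 0.0, 0.0], -0.002, 0.0),  # backward motion keeps sign
        ],
    )
    def test_positional_decomposition(self, displacement, expected_target, expected_nontarget):
        prev = PoseSample(0.0, np.zeros(3), IDENTITY)
        curr = PoseSample(0.011, np.array(displacement), IDENTITY)
        d = frame_delta(prev, curr, self.TARGET)
        assert d.target_delta == pytest.approx(expected_target, abs=1e-15)
        assert d.nontarget_delta == pytest.approx(expected_nontarget, abs=1e-15)
        assert d.rotation_delta == pytest.approx(0.0, abs=1e-9)

    def test_rotation_angle_in_degrees(self):
        q = Rotation.from_euler("x", 5, degrees=True).as_quat(scalar_first=True)
        prev = PoseSample(0.0, np.zeros(3), IDENTITY)
        curr = PoseSample(0.011, np.zeros(3), q)
        d = frame_delta(prev, curr, self.TARGET)
        assert d.rotation_delta == pytest.approx(5.0, abs=1e-9)
        assert 0.0 <= d.rotation_delta <= 180.0

    def test_out_of_order_frames_raise(self):
        a = PoseSample(1.0, np.zeros(3), IDENTITY)
        b = PoseSample(0.5, np.zeros(3), IDENTITY)
        with pytest.raises(ValueError):
            frame_delta(a, b, self.TARGET)

    def test_non_finite_position_raises(self):
        a = PoseSample(0.0, np.zeros(3), IDENTITY)
        b = PoseSample(0.5, np.array([np.nan, 0, 0]), IDENTITY)
        with pytest.raises(ValueError):
            frame_delta(a, b, self.TARGET)


class TestAccumulateAndTrend:
    def test_stationary_controller_is_all_zero(self, cfg):
        summed, trend = accumulate_and_trend(np.zeros(500), cfg)
        assert np.all(summed == 0) and np.all(trend == 0)

    def test_constant_delta_closed_form(self, cfg):
        # summed[k] = (k+1)c; means of arithmetic sequences give
        # trend = c*(w_long - w_short)/2 = 40c once both windows are full
        c = 1e-4
        summed, trend = accumulate_and_trend(np.full(300, c), cfg)
        k = np.arange(300)
        assert np.allclose(summed, (k + 1) * c)
        steady = trend[cfg.w_long - 1 :]
        assert np.allclose(steady, 40 * c, rtol=1e-12)

    def test_impulse_rises_then_decays_within_long_window(self, cfg):
        # a step in the summed series (single positive delta after rest)
        # makes the short MA respond before the long MA: the trend rises,
        # then returns to zero once both windows have absorbed the step
        deltas = np.zeros(400)
        deltas[100] = 0.01
        _, trend = accumulate_and_trend(deltas, cfg)
        assert np.all(trend[:100] == 0.0)
        assert trend[100] > 0 and np.max(trend) <= 0.01
        assert np.allclose(trend[100 + cfg.w_long :], 0.0, atol=1e-15)

    def test_matches_naive_oracle_on_random_streams(self, cfg):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(1, 2000))
            deltas = rng.normal(0, 1e-3, n)
            summed, trend = accumulate_and_trend(deltas, cfg)
            summed_o, trend_o = naive_accumulate_and_trend(deltas, cfg.w_short, cfg.w_long)
            assert np.max(np.abs(summed - summed_o)) < 1e-12
            assert np.max(np.abs(trend - trend_o)) < 1e-12

    def test_empty_sequence_raises(self, cfg):
        with pytest.raises(ValueError):
            accumulate_and_trend(np.array([]), cfg)

    def test_accepts_frame_delta_objects(self, cfg):
        deltas = [FrameDelta(0.001, 0.0, 0.0)] * 100
        summed, _ = accumulate_and_trend(deltas, cfg)
        assert summed[-1] == pytest.approx(0.1)


class TestClassifyFrame:
    QUIET = FrameDelta(0.0, 0.0, 0.0)

    @pytest.mark.parametrize(
        "trend, delta, expected",
        [
            (1e-3, QUIET, INHALATION),  # positive trend => inhalation
            (-1e-3, QUIET, EXHALATION),  # negative trend => exhalation
            (0.0, QUIET, NO_MOVEMENT),
            (2e-4, QUIET, NO_MOVEMENT),  # exactly at the dead-zone edge
            (np.nextafter(2e-4, 1), QUIET, INHALATION),  # just past it
            (-2e-4, QUIET, NO_MOVEMENT),
            (np.nextafter(-2e-4, -1), QUIET, EXHALATION),
            (1e-3, FrameDelta(0.0, 2e-3, 0.0), INHALATION),  # off-axis at threshold: not artifact
            (1e-3, FrameDelta(0.0, np.nextafter(2e-3, 1), 0.0), ARTIFACT),
            (1e-3, FrameDelta(0.0, 0.0, 0.5), INHALATION),  # rotation at threshold
            (1e-3, FrameDelta(0.0, 0.0, np.nextafter(0.5, 1)), ARTIFACT),
            (1e-3, FrameDelta(0.0, 5e-3, 5.0), ARTIFACT),  # both exceeded
            (-1e-3, FrameDelta(0.0, 0.0, 5.0), ARTIFACT),  # artifact beats exhalation
            (0.0, FrameDelta(0.0, 0.0, 5.0), ARTIFACT),  # artifact beats no-movement
        ],
    )
    def test_truth_table(self, cfg, trend, delta, expected):
        assert classify_frame(trend, delta, cfg) == expected


class TestTrack:
    def test_still_stream_is_all_no_movement(self, cfg):
        frames = track(still_stream(int(420 * 90)), cfg)
        assert len(frames) == 420 * 90 - cfg.calibration_frames
        assert np.all(frames.status == NO_MOVEMENT)

    def test_sinusoidal_breathing_alternates_without_artifacts(self, sine_frames):
        counts = sine_frames.status_counts()
        assert counts[ARTIFACT] == 0
        assert counts[INHALATION] > 0.3 * len(sine_frames)
        assert counts[EXHALATION] > 0.3 * len(sine_frames)
        # statuses come in long runs, not chatter: fewer than 4 transitions
        # per 10 s breath cycle on average
        transitions = int(np.sum(sine_frames.status[1:] != sine_frames.status[:-1]))
        assert transitions < 4 * 12

    def test_rotation_burst_flags_exactly_that_span(self, cfg):
        burst = ArtifactEvent(t_start=60.0, t_stop=61.0, lateral_amplitude=0.0, rotation_amplitude=10.0)
        stream = simulate_pose_stream(
            BreathSimParams(duration=120.0, jitter_sd=0.0, artifact_events=[burst], seed=2)
        )
        frames = track(stream, cfg)
        in_span = (frames.t >= burst.t_start) & (frames.t < burst.t_stop)
        flagged = frames.status == ARTIFACT
        # nearly the whole burst is flagged ...
        assert np.mean(flagged[in_span]) > 0.95
        # ... and nothing outside it beyond the single re-entry frame
        near = (frames.t >= burst.t_start - 0.05) & (frames.t < burst.t_stop + 0.05)
        assert not np.any(flagged & ~near)

    def test_every_frame_has_exactly_one_status(self, sine_frames):
        counts = sine_frames.status_counts()
        assert sum(counts.values()) == len(sine_frames)

    def test_causality_under_truncation(self, cfg, sine_stream):
        full = track(sine_stream, cfg)
        k = 2000
        part = track(
            PoseStream(
                t=sine_stream.t[:k], position=sine_stream.position[:k], orientation=sine_stream.orientation[:k]
            ),
            cfg,
        )
        n = len(part)
        assert np.array_equal(part.status, full.status[:n])
        assert np.array_equal(part.trend, full.trend[:n])

    def test_sign_flip_swaps_inhalation_and_exhalation(self, cfg):
        rng = np.random.default_rng(7)
        td = rng.normal(0, 1e-3, 1500)
        nd = np.abs(rng.normal(0, 1e-3, 1500))
        rd = np.abs(rng.normal(0, 0.3, 1500))
        def classify_all(target_deltas):
            _, trend = accumulate_and_trend(target_deltas, cfg)
            return np.array(
                [classify_frame(tr, FrameDelta(d, n_, r), cfg) for tr, d, n_, r in zip(trend, target_deltas, nd, rd)]
            )
        orig = classify_all(td)
        flipped = classify_all(-td)
        swap = {INHALATION: EXHALATION, EXHALATION: INHALATION, NO_MOVEMENT: NO_MOVEMENT, ARTIFACT: ARTIFACT}
        assert np.array_equal(flipped, np.array([swap[s] for s in orig]))

    def test_rig_translation_invariance(self, cfg, sine_stream):
        base = track(sine_stream, cfg)
        shifted = PoseStream(
            t=sine_stream.t,
            position=sine_stream.position + np.array([0.5, -0.25, 1.0]),
            orientation=sine_stream.orientation,
        )
        assert np.array_equal(track(shifted, cfg).status, base.status)

    def test_rig_rotation_invariance(self, cfg, sine_stream):
        base = track(sine_stream, cfg)
        R = Rotation.from_euler("zyx", [30, 45, 10], degrees=True)
        quats = (R * Rotation.from_quat(sine_stream.orientation, scalar_first=True)).as_quat(scalar_first=True)
        rotated = PoseStream(t=sine_stream.t, position=R.apply(sine_stream.position), orientation=quats)
        assert np.array_equal(track(rotated, cfg).status, base.status)


class TestConfigAndStreamValidation:
    def test_window_ordering_enforced(self):
        with pytest.raises(ValueError):
            TrackerConfig(w_short=90, w_long=10)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            TrackerConfig(noise_threshold=-1.0)

    @given(st.integers(min_value=1, max_value=60))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_any_valid_short_window_accepted(self, w):
        assert TrackerConfig(w_short=w, w_long=90).w_short == w

    def test_non_monotone_timestamps_rejected(self, cfg):
        s = still_stream(100)
        t = s.t.copy()
        t[50] = t[49]
        with pytest.raises(ValueError, match="frame 50"):
            PoseStream(t=t, position=s.position, orientation=s.orientation).validate()

    def test_non_unit_quaternion_rejected(self, cfg):
        s = still_stream(100)
        q = s.orientation.copy()
        q[3] = [2.0, 0, 0, 0]
        with pytest.raises(ValueError, match="frame 3"):
            PoseStream(t=s.t, position=s.position, orientation=q).validate()
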
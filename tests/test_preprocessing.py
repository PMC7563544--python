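"""Resampling, ECG filtering, segmentation, and noisy-trial flags."""

import numpy as np
import pytest
from scipy import signal

from intentnet.errors import ConfigError, InsufficientDataError
from intentnet.kinematics import linear_speed, quat_from_axis_angle
from intentnet.preprocessing import (
    EcgRecording,
    KinematicsRecording,
    SensorTrack,
    bandpass_ecg,
    flag_noisy_trials,
    resample_kinematics,
    segment_trials,
    target_distance_series,
)


def _recording_from_channel(x, rate=240.0):
    n = len(x)
    pos = np.column_stack([x, np.zeros(n), np.zeros(n)])
    quat = np.tile([1.0, 0.0, 0.0, 0.0], (n, 1))
    return KinematicsRecording(rate, {"s": SensorTrack(pos, quat)})


class TestResample:
    def test_constant_channel_stays_constant(self):
        rec = _recording_from_channel(np.full(240, 0.7))
        out = resample_kinematics(rec, 256.0)
        assert np.allclose(out.parts["s"].pos[:, 0], 0.7, atol=1e-12)

    def test_length_arithmetic_240_to_256(self):
        rec = _recording_from_channel(np.zeros(240))
        out = resample_kinematics(rec, 256.0)
        assert out.n_frames == 256
        assert out.rate == 256.0

    def test_sine_resampled_within_1e3_of_analytic(self):
        # 5 Hz sine, 10 s at 240 Hz, onto the 256 Hz grid
        t240 = np.arange(2400) / 240.0
        rec = _recording_from_channel(np.sin(2 * np.pi * 5.0 * t240))
        out = resample_kinematics(rec, 256.0)
        t256 = np.arange(out.n_frames) / 256.0
        interior = (t256 > 0.05) & (t256 < t240[-1] - 0.05)
        err = np.abs(out.parts["s"].pos[interior, 0] - np.sin(2 * np.pi * 5.0 * t256[interior]))
        assert err.max() < 1e-3

    def test_band_limited_mean_preserved(self):
        t = np.arange(4800) / 240.0
        x = 0.3 + 0.1 * np.sin(2 * np.pi * 2.0 * t) + 0.05 * np.cos(2 * np.pi * 7.0 * t)
        rec = _recording_from_channel(x)
        out = resample_kinematics(rec, 256.0)
        assert out.parts["s"].pos[:, 0].mean() == pytest.approx(x.mean(), abs=1e-6)

    def test_quaternions_renormalized(self):
        t = np.arange(480) / 240.0
        q = quat_from_axis_angle([0, 0, 1.0], np.radians(50.0) * t)
        pos = np.zeros((480, 3))
        rec = KinematicsRecording(240.0, {"s": SensorTrack(pos, q)})
        out = resample_kinematics(rec, 256.0)
        norms = np.linalg.norm(out.parts["s"].quat, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-12)

    def test_too_few_samples_raise(self):
        with pytest.raises(InsufficientDataError):
            resample_kinematics(_recording_from_channel(np.zeros(3)), 256.0)


class TestBandpass:
    def test_zero_input_zero_output(self):
        ecg = EcgRecording(256.0, np.zeros(2560))
        assert np.allclose(bandpass_ecg(ecg).mv, 0.0)

    def test_passband_sine_amplitude_within_5_percent(self):
        t = np.arange(256 * 20) / 256.0
        ecg = EcgRecording(256.0, np.sin(2 * np.pi * 15.0 * t))
        out = bandpass_ecg(ecg).mv
        amp = np.abs(out[512:-512]).max()
        assert abs(amp - 1.0) < 0.05

    def test_stopband_attenuation_matches_transfer_function(self):
        # zero-phase filtering applies |H|^2; compare the measured 1 Hz
        # attenuation with the squared Butterworth magnitude response
        rate = 256.0
        sos = signal.butter(2, [5.0, 30.0], btype="bandpass", fs=rate, output="sos")
        w, h = signal.sosfreqz(sos, worN=[2 * np.pi * 1.0 / rate])
        expected = np.abs(h[0]) ** 2
        t = np.arange(int(rate * 60)) / rate
        ecg = EcgRecording(rate, np.sin(2 * np.pi * 1.0 * t))
        out = bandpass_ecg(ecg).mv
        measured = np.abs(out[int(10 * rate) : int(50 * rate)]).max()
        assert measured == pytest.approx(expected, rel=0.05)

    def test_zero_phase_no_lag_on_spike_train(self):
        # cross-correlation between a QRS-like train and its filtered
        # version peaks at lag zero
        rate = 256.0
        t = np.arange(int(rate * 30)) / rate
        x = np.zeros_like(t)
        for beat in np.arange(0.5, 29.5, 0.8):
            x += np.exp(-0.5 * ((t - beat) / 0.012) ** 2)
        out = bandpass_ecg(EcgRecording(rate, x)).mv
        c = signal.correlate(out - out.mean(), x - x.mean(), mode="full")
        lags = signal.correlation_lags(len(out), len(x))
        assert lags[np.argmax(c)] == 0

    def test_band_outside_nyquist_raises(self):
        with pytest.raises(ConfigError):
            bandpass_ecg(EcgRecording(256.0, np.zeros(100)), low=5.0, high=200.0)


def _two_trial_series(rate=240.0):
    """Two concatenated synthetic reach/retract trials with known boundaries."""

    def mj(n):
        tau = np.linspace(0, 1, n)
        return 10 * tau**3 - 15 * tau**4 + 6 * tau**5

    rest, move = 120, 110
    prof = np.concatenate(
        [np.zeros(rest), mj(move), np.ones(60), 1 - mj(move), np.zeros(rest)]
    )
    prof = np.concatenate([prof, prof])
    pos = np.column_stack([np.zeros_like(prof), 0.3 * prof, np.zeros_like(prof)])
    speed = linear_speed(pos, rate).values
    n1 = len(prof) // 2
    targets = np.array([[0.0, 0.3, 0.0], [0.0, 0.3, 0.0]])
    windows = [(0, n1), (n1, len(prof))]
    dist = target_distance_series(pos, windows, targets)
    bounds = {
        "f": (rest, rest + move),
        "b": (rest + move + 60, rest + 2 * move + 60),
    }
    return speed, dist, windows, bounds, n1, pos


class TestSegmentation:
    def test_two_concatenated_trials_recovered_in_order(self):
        speed, dist, windows, bounds, n1, _ = _two_trial_series()
        seg = segment_trials(speed, dist, trial_windows=windows)
        assert len(seg) == 2 and all(t.valid for t in seg)
        for k, t in enumerate(seg):
            off = k * n1
            # expected boundaries by the same threshold rule applied to the
            # noiseless speed within each known movement window
            for got, (a, b) in ((t.forward, bounds["f"]), (t.backward, bounds["b"])):
                win = speed[off + a : off + b]
                above = np.flatnonzero(win >= 0.05 * win.max())
                want = (off + a + above[0], off + a + above[-1] + 1)
                assert abs(got[0] - want[0]) <= 3
                assert abs(got[1] - want[1]) <= 3
            assert t.forward[1] <= t.backward[0]

    def test_auto_detected_windows_match_supplied(self):
        speed, dist, windows, _, _, _ = _two_trial_series()
        auto = segment_trials(speed, dist)
        manual = segment_trials(speed, dist, trial_windows=windows)
        assert len(auto) == len(manual) == 2
        for a, m in zip(auto, manual):
            assert abs(a.forward[0] - m.forward[0]) <= 2
            assert abs(a.backward[1] - m.backward[1]) <= 2

    def test_monotone_increasing_distance_is_no_touch(self):
        n = 400
        speed = np.abs(np.sin(np.linspace(0, 3, n)))
        dist = np.linspace(0.3, 0.8, n)
        seg = segment_trials(speed, dist, trial_windows=[(0, n)])
        assert not seg.trials[0].valid
        assert seg.trials[0].reason == "no_touch"

    def test_synthetic_session_recovery_within_3_frames(self, small_session):
        s = small_session
        ee = s.config.end_effector.label
        speed = linear_speed(s.kinematics.parts[ee].pos, s.kinematics.rate).values
        windows = list(zip(s.trials["window_start"], s.trials["window_end"]))
        dist = target_distance_series(
            s.kinematics.parts[ee].pos, windows, s.ground_truth.targets
        )
        seg = segment_trials(speed, dist, trial_windows=windows)
        assert all(t.valid for t in seg)
        for t, gf, gb in zip(
            seg, s.ground_truth.forward_intervals, s.ground_truth.backward_intervals
        ):
            assert abs(t.forward[0] - gf[0]) <= 3
            assert abs(t.forward[1] - gf[1]) <= 3
            assert abs(t.backward[0] - gb[0]) <= 3
            assert abs(t.backward[1] - gb[1]) <= 3


class TestNoisyTrialFlags:
    def test_clean_session_has_no_flags(self, small_session):
        s = small_session
        ee = s.config.end_effector.label
        speed = linear_speed(s.kinematics.parts[ee].pos, s.kinematics.rate).values
        windows = list(zip(s.trials["window_start"], s.trials["window_end"]))
        dist = target_distance_series(
            s.kinematics.parts[ee].pos, windows, s.ground_truth.targets
        )
        seg = segment_trials(speed, dist, trial_windows=windows)
        flagged = flag_noisy_trials(s.kinematics, seg)
        assert all(t.valid for t in flagged)

    def test_injected_spike_flags_exactly_that_trial(self, small_session):
        s = small_session
        kin = KinematicsRecording(
            s.kinematics.rate,
            {k: SensorTrack(v.pos.copy(), v.quat) for k, v in s.kinematics.parts.items()},
        )
        target_trial = 11
        gt_f = s.ground_truth.forward_intervals[target_trial]
        frame = gt_f[0] + 5
        kin.parts["t7"].pos[frame] += np.array([0.15, 0.0, 0.0])  # 15 cm glitch
        ee = s.config.end_effector.label
        speed = linear_speed(kin.parts[ee].pos, kin.rate).values
        windows = list(zip(s.trials["window_start"], s.trials["window_end"]))
        dist = target_distance_series(kin.parts[ee].pos, windows, s.ground_truth.targets)
        seg = segment_trials(speed, dist, trial_windows=windows)
        flagged = flag_noisy_trials(kin, seg, max_pos_jump=0.10)
        bad = [t.trial_id for t in flagged if not t.valid]
        assert bad == [target_trial]
        assert flagged.trials[target_trial].reason == "sensor_noise"

    def test_infinite_threshold_flags_nothing(self, small_session):
        s = small_session
        ee = s.config.end_effector.label
        speed = linear_speed(s.kinematics.parts[ee].pos, s.kinematics.rate).values
        windows = list(zip(s.trials["window_start"], s.trials["window_end"]))
        dist = target_distance_series(
            s.kinematics.parts[ee].pos, windows, s.ground_truth.targets
        )
        seg = segment_trials(speed, dist, trial_windows=windows)
        flagged = flag_noisy_trials(s.kinematics, seg, max_pos_jump=np.inf)
        assert all(t.valid for t in flagged)
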
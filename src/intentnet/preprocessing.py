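"""Preprocessing: resampling, ECG filtering, trial segmentation, noise flags.

Kinematics (nominally 240 Hz) and ECG (nominally 256 Hz) are recorded by
separate devices.  For joint analysis the kinematics are up-sampled onto the
ECG rate with piecewise cubic splines.  The ECG is band-pass filtered
(Butterworth IIR, 5-30 Hz, order 2) to suppress baseline wander and muscle
motion outside the QRS band; filtering is applied forward-backward (zero
phase) so that lead/lag estimates between heart and kinematics are not
biased by filter delay.

Each pointing trial splits into a forward-deliberate reach (speed near zero
at onset, distance to target monotonically decreasing, hand pausing at the
target) and a backward-spontaneous retraction (speed rising away from zero
at the target, settling at the next rest).  "Near zero" is operationalized
as a configurable fraction of the per-trial peak speed, which keeps the rule
scale-free across participants of different size and speed range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import interpolate, signal

from .errors import ConfigError, InsufficientDataError

__all__ = [
    "SensorTrack",
    "KinematicsRecording",
    "EcgRecording",
    "TrialSegment",
    "TrialSegmentation",
    "resample_kinematics",
    "bandpass_ecg",
    "segment_trials",
    "flag_noisy_trials",
    "target_distance_series",
]

#: default fraction of per-trial peak speed regarded as "near zero"
SPEED_THRESHOLD_FRAC = 0.05
#: default hand-to-target distance (m) accepted as a touch
TOUCH_RADIUS_M = 0.02
#: default single-frame position jump (m) that marks a trial as noisy
MAX_POS_JUMP_M = 0.10


@dataclass
class SensorTrack:
    """Position (n, 3) in meters and unit quaternions (n, 4) for one sensor."""

    pos: np.ndarray
    quat: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        self.quat = np.asarray(self.quat, dtype=float)
        if self.pos.shape[0] != self.quat.shape[0]:
            raise ValueError("position and quaternion streams must align")


@dataclass
class KinematicsRecording:
    """Uniformly sampled multi-sensor kinematics."""

    rate: float
    parts: dict[str, SensorTrack]
    t0: float = 0.0

    @property
    def n_frames(self) -> int:
        return next(iter(self.parts.values())).pos.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.rate

    def normalized(self, tol: float = 1e-6) -> "KinematicsRecording":
        """Renormalize quaternions; reject streams further than ``tol`` off unit."""
        parts = {}
        for label, tr in self.parts.items():
            norms = np.linalg.norm(tr.quat, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-2):
                raise ValueError(f"sensor {label}: quaternions far from unit norm")
            parts[label] = SensorTrack(tr.pos, tr.quat / norms[:, None])
        return KinematicsRecording(self.rate, parts, self.t0)


@dataclass
class EcgRecording:
    """Single-channel ECG voltage series (mV), uniformly sampled."""

    rate: float
    mv: np.ndarray
    t0: float = 0.0
    filtered: bool = False
    filter_spec: dict | None = None

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.mv)) / self.rate


@dataclass
class TrialSegment:
    """Forward/backward frame intervals (half-open, 0-based) for one trial."""

    trial_id: int
    forward: tuple[int, int]
    backward: tuple[int, int]
    valid: bool = True
    reason: str = ""  # "" | "no_touch" | "sensor_noise"


@dataclass
class TrialSegmentation:
    """Per-trial segmentation of a session, with validity flags."""

    trials: list[TrialSegment]
    rate: float

    def __iter__(self):
        return iter(self.trials)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def valid_trials(self) -> list[TrialSegment]:
        return [t for t in self.trials if t.valid]

    def at_rate(self, target_rate: float) -> "TrialSegmentation":
        """Rescale frame indices to another sampling rate (rounding)."""
        r = target_rate / self.rate
        out = []
        for t in self.trials:
            out.append(
                replace(
                    t,
                    forward=(int(round(t.forward[0] * r)), int(round(t.forward[1] * r))),
                    backward=(int(round(t.backward[0] * r)), int(round(t.backward[1] * r))),
                )
            )
        return TrialSegmentation(out, target_rate)


# ----------------------------------------------------------------------------
# resampling and filtering
# ----------------------------------------------------------------------------

def resample_kinematics(
    rec: KinematicsRecording, target_rate: float
) -> KinematicsRecording:
    """Resample all channels onto ``target_rate`` with piecewise cubic splines.

    Positions are interpolated per axis; quaternions are sign-continuity
    corrected, interpolated componentwise, and renormalized.  The output grid
    starts at the recording start and holds round(n * target/source) samples
    (the final sample may extrapolate the spline by at most one source
    interval at the tail).
    """
    if target_rate <= 0:
        raise ConfigError("target_rate must be positive")
    n = rec.n_frames
    if n < 4:
        raise InsufficientDataError("need >= 4 samples for cubic-spline resampling")
    t_old = np.arange(n) / rec.rate
    n_out = int(round(n * target_rate / rec.rate))
    t_new = np.arange(n_out) / target_rate

    parts = {}
    for label, tr in rec.parts.items():
        pos = interpolate.CubicSpline(t_old, tr.pos, axis=0)(t_new)
        q = np.array(tr.quat, dtype=float)
        dots = np.sum(q[:-1] * q[1:], axis=1)
        flips = np.concatenate([[1.0], np.cumprod(np.where(dots < 0, -1.0, 1.0))])
        q = q * flips[:, None]
        qi = interpolate.CubicSpline(t_old, q, axis=0)(t_new)
        qi /= np.linalg.norm(qi, axis=1)[:, None]
        parts[label] = SensorTrack(pos, qi)
    return KinematicsRecording(target_rate, parts, rec.t0)


def bandpass_ecg(
    ecg: EcgRecording, low: float = 5.0, high: float = 30.0, order: int = 2
) -> EcgRecording:
    """Zero-phase Butterworth band-pass of the ECG voltage series.

    The stated order refers to the underlying IIR design; forward-backward
    application squares the magnitude response and cancels the phase, so the
    filter introduces no group delay into subsequent lag estimates.
    """
    if not (0.0 < low < high < ecg.rate / 2.0):
        raise ConfigError(
            f"band ({low}, {high}) Hz invalid for Nyquist {ecg.rate / 2} Hz"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=ecg.rate, output="sos")
    out = signal.sosfiltfilt(sos, np.asarray(ecg.mv, dtype=float))
    return EcgRecording(
        ecg.rate,
        out,
        ecg.t0,
        filtered=True,
        filter_spec={"type": "butterworth", "low_hz": low, "high_hz": high,
                     "order": order, "zero_phase": True},
    )


# ----------------------------------------------------------------------------
# trial segmentation
# ----------------------------------------------------------------------------

def target_distance_series(
    ee_pos: np.ndarray,
    trial_windows: list[tuple[int, int]],
    targets: np.ndarray,
) -> np.ndarray:
    """Per-frame distance from the end effector to the current trial's target.

    Frames outside every window take the distance to the nearest window's
    target.
    """
    ee_pos = np.asarray(ee_pos, dtype=float)
    n = len(ee_pos)
    dist = np.empty(n)
    dist.fill(np.nan)
    for (w0, w1), tgt in zip(trial_windows, np.asarray(targets, dtype=float)):
        dist[w0:w1] = np.linalg.norm(ee_pos[w0:w1] - tgt[None, :], axis=1)
    if np.any(np.isnan(dist)):
        # fill gaps with the following (else preceding) trial's target distance
        idx = np.flatnonzero(~np.isnan(dist))
        first, last = idx[0], idx[-1]
        dist[:first] = np.linalg.norm(ee_pos[:first] - targets[0][None, :], axis=1)
        dist[last + 1 :] = np.linalg.norm(ee_pos[last + 1 :] - targets[-1][None, :], axis=1)
        nanmask = np.isnan(dist)
        if np.any(nanmask):
            filled = np.flatnonzero(~nanmask)
            nearest = filled[np.searchsorted(filled, np.flatnonzero(nanmask)).clip(max=len(filled) - 1)]
            dist[nanmask] = dist[nearest]
    return dist


def _detect_trial_windows(
    distance: np.ndarray, touch_radius: float
) -> list[tuple[int, int]]:
    """Split a session into trial windows from touch episodes of the distance.

    A touch episode is a maximal run of frames with distance below
    ``touch_radius``; window boundaries are placed at the midpoints between
    consecutive episodes' ends and starts... more simply, each window ends
    where the next touch episode's approach begins, taken as the midpoint of
    the inter-touch gap.
    """
    near = distance < touch_radius
    if not np.any(near):
        return [(0, len(distance))]
    edges = np.diff(near.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if near[0]:
        starts.insert(0, 0)
    if near[-1]:
        ends.append(len(distance))
    windows = []
    prev = 0
    for k in range(len(starts)):
        nxt = (ends[k] + starts[k + 1]) // 2 if k + 1 < len(starts) else len(distance)
        windows.append((prev, nxt))
        prev = nxt
    return windows


def _segment_one_trial(
    speed: np.ndarray,
    distance: np.ndarray,
    w0: int,
    w1: int,
    frac: float,
    touch_radius: float,
    trial_id: int,
) -> TrialSegment:
    sp = speed[w0:w1]
    di = distance[w0:w1]
    n = len(sp)
    touch = int(np.argmin(di))
    if di[touch] > touch_radius or di[0] <= 2 * touch_radius:
        # never reached the target, or started on it (no forward reach exists)
        return TrialSegment(trial_id, (w0, w0), (w0, w0), valid=False, reason="no_touch")

    # ---- forward reach: around the largest speed peak of the approach
    apex = int(np.argmax(sp[: touch + 1]))
    thr_f = frac * sp[apex]
    below = np.flatnonzero(sp[:apex] < thr_f)
    f_start = int(below[-1]) + 1 if len(below) else 0
    after = np.flatnonzero((sp[apex:] < thr_f) & (di[apex:] <= max(touch_radius, di[touch] * 2)))
    f_end = int(apex + after[0]) if len(after) else touch  # exclusive

    # ---- backward retraction: next speed rise after the pause at the target
    rest = np.flatnonzero(sp[f_end:] >= thr_f)
    if len(rest) == 0:
        return TrialSegment(trial_id, (w0, w0), (w0, w0), valid=False, reason="no_touch")
    b_probe = f_end + int(rest[0])
    apex_b = b_probe + int(np.argmax(sp[b_probe:]))
    thr_b = frac * sp[apex_b]
    below_b = np.flatnonzero(sp[f_end:apex_b] < thr_b)
    b_start = f_end + int(below_b[-1]) + 1 if len(below_b) else b_probe
    after_b = np.flatnonzero(sp[apex_b:] < thr_b)
    b_end = int(apex_b + after_b[0]) if len(after_b) else n

    if f_end <= f_start or b_end <= b_start:
        return TrialSegment(trial_id, (w0, w0), (w0, w0), valid=False, reason="no_touch")
    return TrialSegment(
        trial_id, (w0 + f_start, w0 + f_end), (w0 + b_start, w0 + b_end)
    )


def segment_trials(
    end_effector_speed: np.ndarray,
    distance_to_target: np.ndarray,
    speed_threshold_frac: float = SPEED_THRESHOLD_FRAC,
    *,
    trial_windows: list[tuple[int, int]] | None = None,
    touch_radius: float = TOUCH_RADIUS_M,
    rate: float = 240.0,
    smooth_frames: int = 1,
) -> TrialSegmentation:
    """Separate each pointing trial into forward and backward intervals.

    The forward reach runs from the last near-zero-speed frame before the
    distance to the target begins its monotone decrease, to the frame where
    the hand pauses at the target (speed back below threshold with the
    distance within ``touch_radius``).  The backward retraction runs from
    the speed rising away from zero at the target to the next near-zero
    rest.  "Near zero" means below ``speed_threshold_frac`` times the
    per-trial peak speed of the segment's own speed excursion.

    ``trial_windows`` (half-open frame intervals) may be supplied from the
    session's event log; otherwise windows are detected from touch episodes
    of the distance series.  Trials whose distance never comes within
    ``touch_radius`` are marked invalid with reason ``no_touch``.

    Threshold crossings are located on a lightly smoothed copy of the speed
    (symmetric ``smooth_frames``-point moving average) so that measurement
    noise does not jitter the detected boundaries.
    """
    speed = np.asarray(end_effector_speed, dtype=float)
    distance = np.asarray(distance_to_target, dtype=float)
    if speed.shape != distance.shape:
        raise ValueError("speed and distance series must align")
    if not 0 < speed_threshold_frac < 1:
        raise ConfigError("speed_threshold_frac must be in (0, 1)")
    if smooth_frames > 1 and len(speed) > smooth_frames:
        kernel = np.ones(smooth_frames | 1) / float(smooth_frames | 1)
        speed = np.convolve(speed, kernel, mode="same")
    if trial_windows is None:
        trial_windows = _detect_trial_windows(distance, touch_radius)
    segments = [
        _segment_one_trial(speed, distance, w0, w1, speed_threshold_frac, touch_radius, k)
        for k, (w0, w1) in enumerate(trial_windows)
    ]
    return TrialSegmentation(segments, rate)


def flag_noisy_trials(
    rec: KinematicsRecording,
    seg: TrialSegmentation,
    max_pos_jump: float = MAX_POS_JUMP_M,
) -> TrialSegmentation:
    """Invalidate trials containing implausible single-frame position jumps.

    Any sensor jumping more than ``max_pos_jump`` meters between consecutive
    frames within a trial's extent (forward start to backward end) marks the
    trial invalid with reason ``sensor_noise``.
    """
    if not np.isfinite(max_pos_jump):
        return TrialSegmentation(list(seg.trials), seg.rate)
    jumps = np.zeros(rec.n_frames - 1)
    for tr in rec.parts.values():
        jumps = np.maximum(jumps, np.linalg.norm(np.diff(tr.pos, axis=0), axis=1))
    out = []
    for t in seg.trials:
        if t.valid:
            a, b = t.forward[0], t.backward[1]
            if b > a and np.any(jumps[a : max(a, b - 1)] > max_pos_jump):
                out.append(replace(t, valid=False, reason="sensor_noise"))
                continue
        out.append(t)
    return TrialSegmentation(out, seg.rate)
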
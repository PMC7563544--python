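"""Synthetic pointing-task sessions: kinematics, ECG, and ground truth.

The generator emulates a seated pointing experiment: on each trial the
performing hand reaches forward to touch a target (deliberate, instructed)
and then retracts (spontaneous, uninstructed).  Ten upper-body sensors
record 3-D position and orientation at 240 Hz; a single-channel ECG records
at 256 Hz.  Every statistical structure the downstream analysis measures is
injected explicitly and reported as ground truth:

* **Reach geometry** — the end effector follows a minimum-jerk trajectory
  (bell-shaped speed, monotone decreasing distance to the target), with
  independently configured movement-locked fluctuation amplitudes per
  segment (the retraction is the more variable one).
* **Micro-movement spike laws** — each sensor's orientation stream is built
  so that the angular-acceleration magnitudes recovered by the analysis
  equal a designed oscillation whose standardized spike amplitudes follow
  the configured Gamma(shape, scale) law for that (segment x side) cell,
  truncated to the representable interval (see note below).  The
  construction inverts the analysis' own central-difference operators on
  the even/odd frame lattices, so recovery is exact at interior frames.
* **Cross-body coupling** — non-end-effector sensors move as attenuated,
  time-shifted copies of the reach profile plus an independent smooth
  background process; the coupled amplitude per (segment x side) cell sets
  the cross-correlation level.
* **Heart lead/lag** — the ECG contains a QRS bump train plus a band-limited
  component whose amplitude envelope is a movement-locked bump offset by a
  configurable signed lead per segment; side differences arise from an
  anticipatory advance of non-performing body parts.

Note on amplitude laws: spike standardization p/(p + mean(min)) of a
nonnegative waveform always yields amplitudes in (1/2, 1], so configured
Gamma cells must place essentially all mass there; the defaults (shape 250,
cell means 0.64-0.80) keep every mean at least 4 standard deviations below
the ceiling, leaving well under 1% truncated mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .errors import ConfigError
from .kinematics import quat_from_axis_angle, quat_multiply
from .preprocessing import EcgRecording, KinematicsRecording, SensorTrack

__all__ = [
    "BodyPart",
    "SessionConfig",
    "GroundTruth",
    "SegmentEvent",
    "SessionData",
    "default_body_parts",
    "generate_trial_kinematics",
    "generate_ecg",
    "generate_session",
]

SEGMENTS = ("forward", "backward")
SIDES = ("performing", "non_performing")
MIDLINE = "midline"


@dataclass(frozen=True)
class BodyPart:
    label: str
    side: str  # performing / non_performing / midline
    is_end_effector: bool = False


def default_body_parts(handedness: str = "right") -> tuple[BodyPart, ...]:
    """The ten analyzed upper-body sensors, side-tagged by handedness.

    Dominant side: scapula, upper arm, forearm, index finger (end effector).
    Contralateral side: scapula, upper arm, forearm, hand.  Forehead and T7
    sit on the midline and never enter side contrasts.
    """
    if handedness not in ("left", "right"):
        raise ConfigError(f"unknown handedness {handedness!r}")
    dom = handedness
    non = "left" if dom == "right" else "right"
    return (
        BodyPart("forehead", MIDLINE),
        BodyPart("t7", MIDLINE),
        BodyPart(f"{dom}_scapula", "performing"),
        BodyPart(f"{non}_scapula", "non_performing"),
        BodyPart(f"{dom}_upper_arm", "performing"),
        BodyPart(f"{non}_upper_arm", "non_performing"),
        BodyPart(f"{dom}_forearm", "performing"),
        BodyPart(f"{non}_forearm", "non_performing"),
        BodyPart(f"{non}_hand", "non_performing"),
        BodyPart(f"{dom}_index", "performing", is_end_effector=True),
    )


def _default_gamma_params() -> dict[tuple[str, str], tuple[float, float]]:
    # cell means (shape*scale): fwd/perf .80, fwd/np .73, bwd/perf .71,
    # bwd/np .64 — each mean sits >= 4 sd below the amplitude ceiling at 1,
    # so the truncation to the representable interval is negligible
    return {
        ("forward", "performing"): (250.0, 0.00320),
        ("forward", "non_performing"): (250.0, 0.00292),
        ("backward", "performing"): (250.0, 0.00284),
        ("backward", "non_performing"): (250.0, 0.00256),
    }


def _default_coupling() -> dict[tuple[str, str], float]:
    return {
        ("forward", "performing"): 0.85,
        ("forward", "non_performing"): 0.70,
        ("backward", "performing"): 0.65,
        ("backward", "non_performing"): 0.50,
    }


_ATTENUATION = {
    "index": 1.0,
    "hand": 0.40,
    "forearm": 0.70,
    "upper_arm": 0.45,
    "scapula": 0.18,
    "forehead": 0.12,
    "t7": 0.10,
}


def _attenuation(label: str) -> float:
    for key, val in _ATTENUATION.items():
        if label.endswith(key) or label == key:
            return val
    return 0.3


@dataclass
class SessionConfig:
    """Everything the generator needs; defaults are the emulated study
    conditions (session length, rates, variability structure)."""

    n_trials: int = 180
    frame_rate_kin: float = 240.0
    frame_rate_ecg: float = 256.0
    handedness: str = "right"
    body_parts: tuple[BodyPart, ...] | None = None
    gamma_params: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=_default_gamma_params
    )
    coupling: float | dict[tuple[str, str], float] = field(default_factory=_default_coupling)
    heart_rate: float = 72.0
    heart_lead_ms: dict[str, float] = field(
        default_factory=lambda: {"forward": 150.0, "backward": -50.0}
    )
    anticipation_ms: dict[str, float] = field(
        default_factory=lambda: {"performing": 0.0, "non_performing": 100.0, MIDLINE: 50.0}
    )
    noise_sd: float = 0.0002          # position measurement noise, m
    path_fluct_m: dict[str, float] = field(
        default_factory=lambda: {"forward": 0.0006, "backward": 0.0015}
    )
    background_frac: float = 0.20     # background speed / coupled peak speed
    reach_amplitude_m: float = 0.35
    forward_duration_s: float = 0.45
    backward_duration_s: float = 0.50
    dwell_s: float = 0.20
    rest_s: float = 0.50              # pre- and post-rest per trial
    timing_jitter_s: float = 0.04
    speed_threshold_frac: float = 0.05  # defines ground-truth segment edges
    # ECG waveform parameters
    qrs_amp_mv: float = 1.0
    carrier_amp_mv: float = 0.25
    carrier_freq_hz: float = 12.0
    modulation_depth: float = 0.9
    ecg_noise_sd_mv: float = 0.02
    clock_offset_s: float | None = 0.0  # None -> drawn uniform(-1, 1) s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.body_parts is None:
            self.body_parts = default_body_parts(self.handedness)
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        for rate in (self.frame_rate_kin, self.frame_rate_ecg, self.heart_rate):
            if rate <= 0:
                raise ConfigError("all rates must be positive")
        if not (20.0 < self.heart_rate < 250.0):
            raise ConfigError("heart_rate must lie in (20, 250) bpm")
        for cell, (shape, scale) in self.gamma_params.items():
            if shape <= 0 or scale <= 0:
                raise ConfigError(f"gamma shape/scale must be positive ({cell})")
        ee = [p for p in self.body_parts if p.is_end_effector]
        if len(ee) != 1 or ee[0].side != "performing":
            raise ConfigError("exactly one end effector on the performing side required")
        for seg in SEGMENTS:
            for side in SIDES:
                c = self.cell_coupling(seg, side)
                if not 0.0 <= c <= 1.0:
                    raise ConfigError("coupling must lie in [0, 1]")

    # -- cell accessors (midline cells average the two sides) ---------------
    def cell_gamma(self, segment: str, side: str) -> tuple[float, float]:
        if side == MIDLINE:
            a1, b1 = self.gamma_params[(segment, "performing")]
            a2, b2 = self.gamma_params[(segment, "non_performing")]
            return 0.5 * (a1 + a2), 0.5 * (b1 + b2)
        return self.gamma_params[(segment, side)]

    def cell_coupling(self, segment: str, side: str) -> float:
        if isinstance(self.coupling, dict):
            if side == MIDLINE:
                return 0.5 * (
                    self.coupling[(segment, "performing")]
                    + self.coupling[(segment, "non_performing")]
                )
            return self.coupling[(segment, side)]
        return float(self.coupling)

    @property
    def end_effector(self) -> BodyPart:
        return next(p for p in self.body_parts if p.is_end_effector)


@dataclass
class SegmentEvent:
    """A movement segment's speed-peak time (kinematics clock, seconds)."""

    t_peak_s: float
    segment: str
    duration_s: float


@dataclass
class GroundTruth:
    """Injected truth for a generated session (frame indices at 240 Hz)."""

    forward_intervals: list[tuple[int, int]]
    backward_intervals: list[tuple[int, int]]
    trial_windows: list[tuple[int, int]]
    targets: np.ndarray
    gamma_params: dict[tuple[str, str], tuple[float, float]]
    heart_lead_ms: dict[str, float]
    anticipation_ms: dict[str, float]
    clock_offset_s: float
    events: list[SegmentEvent]

    def __post_init__(self) -> None:
        for fwd, bwd in zip(self.forward_intervals, self.backward_intervals):
            if not (fwd[0] < fwd[1] <= bwd[0] < bwd[1]):
                raise ValueError("forward must precede backward, non-overlapping")


@dataclass
class SessionData:
    kinematics: KinematicsRecording
    ecg: EcgRecording
    trials: pd.DataFrame
    ground_truth: GroundTruth
    config: SessionConfig


# ----------------------------------------------------------------------------
# building blocks
# ----------------------------------------------------------------------------

def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile s(tau) on [0, 1], s(0)=0, s(1)=1."""
    t = np.clip(tau, 0.0, 1.0)
    return 10 * t**3 - 15 * t**4 + 6 * t**5


def minimum_jerk_bell(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk speed bell on [0, 1] (max 1 at tau = 1/2)."""
    t = np.clip(tau, 0.0, 1.0)
    return 16.0 * t**2 * (1.0 - t) ** 2


def _truncated_gamma(
    rng: np.random.Generator, shape: float, scale: float, lo: float, hi: float, n: int
) -> np.ndarray:
    qlo = stats.gamma.cdf(lo, shape, scale=scale)
    qhi = stats.gamma.cdf(hi, shape, scale=scale)
    if qhi - qlo < 1e-9:
        raise ConfigError(
            f"Gamma(shape={shape}, scale={scale}) places no mass in ({lo}, {hi}); "
            "spike amplitudes of a nonnegative waveform live in (1/2, 1]"
        )
    u = rng.uniform(qlo, qhi, size=n)
    return stats.gamma.ppf(u, shape, scale=scale)


def _design_segment_accel(
    rng: np.random.Generator,
    n_frames: int,
    shape: float,
    scale: float,
    base_level: float = 40.0,
    amp_lo: float = 0.52,
    amp_hi: float = 0.999,
) -> np.ndarray:
    """Strictly positive oscillation whose spike amplitudes follow the law.

    Knots alternate valley / peak at random 3-5 frame gaps; valleys sit near
    ``base_level`` (deg/s^2) with a small jitter, and each peak p is solved
    from a truncated-Gamma amplitude draw a via p = mean(valleys) * a/(1-a).
    Half-cosine interpolation between knots puts a strict extremum exactly
    at each knot and nothing in between.
    """
    if n_frames < 12:
        return np.full(n_frames, base_level)
    positions = [0]
    while positions[-1] < n_frames - 1:
        positions.append(positions[-1] + int(rng.integers(3, 6)))
    positions[-1] = n_frames - 1
    if len(positions) >= 2 and positions[-1] - positions[-2] < 2:
        positions.pop(-2)
    k = len(positions)
    n_valleys = (k + 1) // 2
    valleys = base_level * (1.0 + rng.uniform(-0.02, 0.02, size=n_valleys))
    n_peaks = k // 2
    amps = _truncated_gamma(rng, shape, scale, amp_lo, amp_hi, max(n_peaks, 1))
    values = np.empty(k)
    values[0::2] = valleys
    for i, idx in enumerate(range(1, k, 2)):
        vbar = 0.5 * (values[idx - 1] + (values[idx + 1] if idx + 1 < k else values[idx - 1]))
        values[idx] = vbar * amps[i] / (1.0 - amps[i])

    out = np.empty(n_frames)
    for a, b, va, vb in zip(positions[:-1], positions[1:], values[:-1], values[1:]):
        x = np.arange(a, b + 1) - a
        out[a : b + 1] = va + (vb - va) * 0.5 * (1.0 - np.cos(np.pi * x / (b - a)))
    return out


def _integrate_lattice(accel: np.ndarray, rate: float) -> np.ndarray:
    """Rotation angle whose analysis-side angular acceleration equals ``accel``.

    The analysis computes angular speed by central differences of the
    cumulative rotation angle and angular acceleration by central
    differences of that, i.e. AA[k] = (theta[k+2] - 2 theta[k] +
    theta[k-2]) * rate^2 / 4.  Even and odd frame lattices decouple, so a
    double cumulative sum per lattice reproduces ``accel`` exactly at
    interior frames.
    """
    n = len(accel)
    theta = np.zeros(n)
    for parity in (0, 1):
        idx = np.arange(parity, n, 2)
        if len(idx) < 2:
            continue
        inc = 4.0 * accel[idx] / rate**2
        slope = np.cumsum(inc)
        theta[idx[1:]] = np.cumsum(slope[:-1])
    return theta


def _fill_decay(accel: np.ndarray, rate: float, start: int, end: int) -> None:
    """Write constant negative acceleration into [start, end) per lattice so
    the accumulated rotation slope returns exactly to zero."""
    for parity in (0, 1):
        idx = np.arange(parity, len(accel), 2)
        before = idx[idx < start]
        inside = idx[(idx >= start) & (idx < end)]
        if len(inside) == 0:
            continue
        slope = np.sum(4.0 * accel[before] / rate**2)
        accel[inside] = -slope * rate**2 / (4.0 * len(inside))


def _smooth_noise(rng: np.random.Generator, n: int, rate: float, cutoff_hz: float,
                  sd: float, shape: tuple[int, ...] = ()) -> np.ndarray:
    """Low-passed white noise rescaled to the requested standard deviation."""
    raw = rng.standard_normal((n, *shape) if shape else n)
    if n > 18:
        sos = sps.butter(2, cutoff_hz, fs=rate, output="sos")
        raw = sps.sosfiltfilt(sos, raw, axis=0)
    s = raw.std(axis=0)
    s = np.where(s > 0, s, 1.0)
    return raw / s * sd


def _band_noise(rng: np.random.Generator, n: int, rate: float,
                band: tuple[float, float]) -> np.ndarray:
    raw = rng.standard_normal(n)
    if n > 24:
        sos = sps.butter(2, band, btype="bandpass", fs=rate, output="sos")
        raw = sps.sosfiltfilt(sos, raw)
    s = raw.std()
    return raw / (s if s > 0 else 1.0)


# ----------------------------------------------------------------------------
# per-session deterministic geometry
# ----------------------------------------------------------------------------

def _session_geometry(config: SessionConfig) -> dict[str, dict]:
    """Anchors, movement directions, and rotation axes per part (stable
    across trials of a session; derived from the session seed only)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 777001]))
    geo: dict[str, dict] = {}
    for part in config.body_parts:
        anchor = rng.uniform(-0.3, 0.3, size=3)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        if part.is_end_effector:
            anchor = np.zeros(3)
            direction = np.array([0.0, 1.0, 0.0])
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        q0 = rng.standard_normal(4)
        q0 /= np.linalg.norm(q0)
        perp = np.cross(direction, rng.standard_normal(3))
        perp /= np.linalg.norm(perp)
        geo[part.label] = {
            "anchor": anchor, "direction": direction, "axis": axis, "q0": q0,
            "perp": perp, "alpha": _attenuation(part.label), "side": part.side,
            "delta_s": 0.0 if part.is_end_effector
            else config.anticipation_ms.get(part.side, 0.0) / 1000.0,
        }
    return geo


# ----------------------------------------------------------------------------
# trial kinematics
# ----------------------------------------------------------------------------

@dataclass
class TrialFragment:
    parts: dict[str, SensorTrack]
    theta_deg: dict[str, np.ndarray]
    n_frames: int
    f0: int
    f1: int
    b0: int
    b1: int
    gt_forward: tuple[int, int]
    gt_backward: tuple[int, int]
    target: np.ndarray
    events: list[SegmentEvent]  # times local to the fragment

    def as_recording(self, rate: float) -> KinematicsRecording:
        return KinematicsRecording(rate, self.parts)


def generate_trial_kinematics(
    config: SessionConfig, trial_index: int, rng: np.random.Generator | None = None
) -> TrialFragment:
    """One trial: pre-rest, forward reach, dwell, backward retraction, post-rest.

    Deterministic in (config.seed, trial_index) when ``rng`` is not given.
    """
    if trial_index >= config.n_trials or trial_index < 0:
        raise IndexError(f"trial_index {trial_index} out of range [0, {config.n_trials})")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, trial_index]))
    rate = config.frame_rate_kin
    jit = config.timing_jitter_s
    geo = _session_geometry(config)

    pre = config.rest_s + (0.7 if trial_index == 0 else 0.0) + rng.uniform(-jit, jit)
    tf = config.forward_duration_s + rng.uniform(-jit, jit)
    dw = config.dwell_s + rng.uniform(-1.5 * jit, 1.5 * jit)
    tb = config.backward_duration_s + rng.uniform(-jit, jit)
    post = config.rest_s + rng.uniform(-jit, jit)

    f0 = int(round(pre * rate))
    lf = max(12, int(round(tf * rate)))
    ld = max(8, int(round(dw * rate)))
    lb = max(12, int(round(tb * rate)))
    lp = max(8, int(round(post * rate)))
    f1, b0 = f0 + lf, f0 + lf + ld
    b1 = b0 + lb
    n = b1 + lp

    reach = config.reach_amplitude_m * (1.0 + rng.uniform(-0.05, 0.05))
    lateral = rng.uniform(-0.15, 0.15)
    ee_dir = np.array([lateral, 1.0, -0.2])
    ee_dir /= np.linalg.norm(ee_dir)

    # unit displacement profile: 0 -> 1 over the reach, 1 -> 0 over the return
    profile = np.zeros(n)
    profile[f0:f1] = minimum_jerk(np.arange(lf) / (lf - 1))
    profile[f1:b0] = 1.0
    profile[b0:b1] = minimum_jerk(1.0 - np.arange(lb) / (lb - 1))

    # segment-windowed fluctuation of the end effector; the windowed ripple
    # is rescaled so each segment's realized speed-ripple RMS equals the
    # configured amplitude times the band's center angular frequency
    fluct = np.zeros(n)
    for (a, b), seg in (((f0, f1), "forward"), ((b0, b1), "backward")):
        bell = minimum_jerk_bell(np.arange(b - a) / (b - a - 1))
        w = bell * _band_noise(rng, b - a, rate, (6.0, 12.0))
        ripple = np.gradient(w, 1.0 / rate).std()
        target = config.path_fluct_m[seg] * 2.0 * np.pi * 9.0
        fluct[a:b] = w / ripple * target if ripple > 0 else 0.0

    v_nominal = 1.875 * config.reach_amplitude_m / config.forward_duration_s

    parts: dict[str, SensorTrack] = {}
    thetas: dict[str, np.ndarray] = {}
    for part in config.body_parts:
        g = geo[part.label]
        shift = int(round(g["delta_s"] * rate))  # anticipatory advance, frames

        if part.is_end_effector:
            disp = reach * profile
            pos = g["anchor"][None, :] + disp[:, None] * ee_dir[None, :]
            # fluctuation split between the movement direction (perturbing
            # speed directly) and the transverse direction (path wiggle)
            perp = np.cross(ee_dir, [0.0, 0.0, 1.0])
            perp /= np.linalg.norm(perp)
            pos += fluct[:, None] * (0.7071 * ee_dir + 0.7071 * perp)[None, :]
        else:
            cf = config.cell_coupling("forward", part.side)
            cb = config.cell_coupling("backward", part.side)
            cp = np.zeros(n)
            cp[f0:f1] = cf * profile[f0:f1]
            cp[f1:b0] = cf
            cp[b0:b1] = cf - cb * (1.0 - profile[b0:b1])
            resid = cf - cb
            cp[b1:] = resid * (1.0 - minimum_jerk(np.arange(n - b1) / max(n - b1 - 1, 1)))
            if shift > 0:
                cp = np.concatenate([cp[shift:], np.full(shift, cp[-1])])
            bg = _band_noise(rng, n, rate, (0.8, 3.5))
            bg_speed = np.gradient(bg, 1.0 / rate)
            sd = bg_speed.std()
            bg = bg / (sd if sd > 0 else 1.0) * config.background_frac * v_nominal
            taper = sps.windows.tukey(n, alpha=min(0.5, 2 * 0.2 * rate / n))
            pos = (
                g["anchor"][None, :]
                + (g["alpha"] * reach * cp)[:, None] * g["direction"][None, :]
                + (g["alpha"] * bg * taper)[:, None] * g["perp"][None, :]
            )

        pos = pos + _smooth_noise(rng, n, rate, 10.0, config.noise_sd, (3,))

        # orientation stream carrying the configured spike-amplitude law;
        # the angular activity is aligned with the end effector's segments so
        # that segment slicing recovers exactly the designed spike law
        accel = np.zeros(n)
        for (a, b), seg in (((f0, f1), "forward"), ((b0, b1), "backward")):
            sh, sc = config.cell_gamma(seg, part.side)
            accel[a:b] = _design_segment_accel(rng, b - a, sh, sc)
        _fill_decay(accel, rate, f1, b0)
        _fill_decay(accel, rate, b1, n)
        theta = _integrate_lattice(accel, rate)
        # a constant baseline rotation rate keeps theta strictly increasing
        # (the quaternion log-map only exposes |d theta|, so any local dip
        # from even/odd lattice drift would fold and corrupt the designed
        # waveform); a linear ramp adds nothing to the second difference
        d = np.diff(theta)
        base_rate = (max(0.0, -d.min()) * rate + 20.0)
        theta = theta + base_rate * np.arange(n) / rate
        quat = quat_multiply(
            np.broadcast_to(g["q0"], (n, 4)),
            quat_from_axis_angle(g["axis"], np.radians(theta)),
        )
        parts[part.label] = SensorTrack(pos, quat)
        thetas[part.label] = theta

    # ground truth from the noiseless end-effector speed profile
    speed0 = reach * np.abs(np.gradient(profile, 1.0 / rate))
    gt_fwd = _threshold_interval(speed0, f0, f1, config.speed_threshold_frac)
    gt_bwd = _threshold_interval(speed0, b0, b1, config.speed_threshold_frac)
    target = geo[config.end_effector.label]["anchor"] + reach * ee_dir
    events = [
        SegmentEvent((f0 + 0.5 * (lf - 1)) / rate, "forward", lf / rate),
        SegmentEvent((b0 + 0.5 * (lb - 1)) / rate, "backward", lb / rate),
    ]
    return TrialFragment(parts, thetas, n, f0, f1, b0, b1, gt_fwd, gt_bwd, target, events)


def _threshold_interval(
    speed: np.ndarray, a: int, b: int, frac: float
) -> tuple[int, int]:
    win = speed[a:b]
    above = np.flatnonzero(win >= frac * win.max())
    return a + int(above[0]), a + int(above[-1]) + 1


# ----------------------------------------------------------------------------
# ECG
# ----------------------------------------------------------------------------

def _qrs_template(t: np.ndarray, amp: float) -> np.ndarray:
    r = amp * np.exp(-0.5 * (t / 0.012) ** 2)
    q = -0.15 * amp * np.exp(-0.5 * ((t + 0.035) / 0.015) ** 2)
    s = -0.25 * amp * np.exp(-0.5 * ((t - 0.035) / 0.015) ** 2)
    return r + q + s


def generate_ecg(
    config: SessionConfig,
    events: list[SegmentEvent],
    duration_s: float,
    rng: np.random.Generator | None = None,
    time_offset_s: float = 0.0,
) -> EcgRecording:
    """Template-based ECG with a movement-locked autonomic modulation.

    A QRS bump train beats at the configured heart rate.  A band-limited
    (carrier) component's amplitude follows an envelope of minimum-jerk
    bumps, one per movement segment, each centered ``heart_lead_ms`` before
    (positive) or after (negative) that segment's speed peak.  Sample k
    takes the waveform value at time ``k / rate + time_offset_s`` on the
    kinematics clock, emulating an unsynchronized device clock.
    """
    if not (20.0 < config.heart_rate < 250.0):
        raise ConfigError("heart_rate must lie in (20, 250) bpm")
    starts = [e.t_peak_s - 0.5 * e.duration_s for e in events]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ValueError("events must be sorted in time")
    ends = [e.t_peak_s + 0.5 * e.duration_s for e in events]
    if any(e > s for e, s in zip(ends, starts[1:])):
        raise ValueError("events must be non-overlapping")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 424242]))
    rate = config.frame_rate_ecg
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate + time_offset_s

    mv = np.zeros(n)
    period = 60.0 / config.heart_rate
    t_lo, t_hi = t[0], t[-1]
    k0 = int(np.floor((t_lo - 0.2) / period))
    k1 = int(np.ceil((t_hi + 0.2) / period))
    half = int(round(0.12 * rate))
    for k in range(k0, k1 + 1):
        tk = k * period
        c = int(round((tk - time_offset_s) * rate))
        a, b = max(0, c - half), min(n, c + half + 1)
        if b > a:
            mv[a:b] += _qrs_template(t[a:b] - tk, config.qrs_amp_mv)

    env = np.zeros(n)
    for e in events:
        lead = config.heart_lead_ms.get(e.segment, 0.0) / 1000.0
        center = e.t_peak_s - lead
        tau = (t - center) / e.duration_s + 0.5
        m = (tau >= 0.0) & (tau <= 1.0)
        env[m] += minimum_jerk_bell(tau[m])

    phase = rng.uniform(0.0, 2 * np.pi)
    mv += (
        config.carrier_amp_mv
        * (1.0 + config.modulation_depth * env)
        * np.sin(2 * np.pi * config.carrier_freq_hz * t + phase)
    )
    mv += rng.normal(0.0, config.ecg_noise_sd_mv, size=n)
    return EcgRecording(rate, mv, t0=0.0, filtered=False)


# ----------------------------------------------------------------------------
# session assembly
# ----------------------------------------------------------------------------

def generate_session(config: SessionConfig) -> SessionData:
    """Generate a full session: kinematics, ECG, trials table, ground truth."""
    rate = config.frame_rate_kin
    geo = _session_geometry(config)
    rng_sess = np.random.default_rng(np.random.SeedSequence([config.seed, 999983]))
    offset = (
        float(rng_sess.uniform(-1.0, 1.0))
        if config.clock_offset_s is None
        else float(config.clock_offset_s)
    )

    pos_chunks = {p.label: [] for p in config.body_parts}
    quat_chunks = {p.label: [] for p in config.body_parts}
    theta_offset = {p.label: 0.0 for p in config.body_parts}
    fwd, bwd, windows, targets, events = [], [], [], [], []
    frame0 = 0
    for i in range(config.n_trials):
        frag = generate_trial_kinematics(config, i)
        for part in config.body_parts:
            lab = part.label
            pos_chunks[lab].append(frag.parts[lab].pos)
            theta = frag.theta_deg[lab] + theta_offset[lab]
            quat_chunks[lab].append(
                quat_multiply(
                    np.broadcast_to(geo[lab]["q0"], (frag.n_frames, 4)),
                    quat_from_axis_angle(geo[lab]["axis"], np.radians(theta)),
                )
            )
            theta_offset[lab] = theta[-1]
        fwd.append((frame0 + frag.gt_forward[0], frame0 + frag.gt_forward[1]))
        bwd.append((frame0 + frag.gt_backward[0], frame0 + frag.gt_backward[1]))
        windows.append((frame0, frame0 + frag.n_frames))
        targets.append(frag.target)
        for e in frag.events:
            events.append(SegmentEvent(frame0 / rate + e.t_peak_s, e.segment, e.duration_s))
        frame0 += frag.n_frames

    parts = {
        lab: SensorTrack(np.vstack(pos_chunks[lab]), np.vstack(quat_chunks[lab]))
        for lab in pos_chunks
    }
    kin = KinematicsRecording(rate, parts)
    duration = frame0 / rate
    ecg = generate_ecg(config, events, duration, time_offset_s=offset)

    trials = pd.DataFrame(
        {
            "trial_id": np.arange(config.n_trials),
            "window_start": [w[0] for w in windows],
            "window_end": [w[1] for w in windows],
            "target_x": [t[0] for t in targets],
            "target_y": [t[1] for t in targets],
            "target_z": [t[2] for t in targets],
        }
    )
    gt = GroundTruth(
        fwd, bwd, windows, np.array(targets),
        dict(config.gamma_params), dict(config.heart_lead_ms),
        dict(config.anticipation_ms), offset, events,
    )
    return SessionData(kin, ecg, trials, gt, config)
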
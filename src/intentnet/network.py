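"""Cross-correlation connectivity networks over body parts and the heart.

Pairwise maximal cross-correlations between linear-speed waveforms define a
weighted undirected graph over the body's sensor grid: the ij edge weight is
the maximum of the normalized cross-correlation magnitude over a bounded lag
window, and the signed lag of that maximum records which node leads.  From
the adjacency matrix, per-node weighted clustering coefficients quantify
functional segregation (self-emerging kinematic synergies):

    C_i = 2 t_i / (k_i (k_i - 1)),

where t_i is the sum over neighbor pairs (j, h) of the geometric mean
(w_ij w_ih w_jh)^(1/3) of max-normalized edge weights and k_i the number of
nonzero edges at node i.

The heart joins the network through per-trial cross-correlations between
the filtered ECG's amplitude envelope and each body part's linear speed,
yielding a coefficient, a signed lead/lag (positive = heart leads the
movement), and an EMD between the part's and the heart's MMS histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import InsufficientDataError, RateMismatchError
from .preprocessing import EcgRecording, TrialSegmentation
from .stochastic import Histogram, emd

__all__ = [
    "XCorrResult",
    "AdjacencyMatrix",
    "NodeMetrics",
    "HeartEdge",
    "max_xcorr",
    "windowed_xcorr",
    "build_adjacency",
    "clustering_coefficients",
    "ecg_envelope",
    "heart_body_connectivity",
]

MAX_LAG_S = 1.0          # generic lag window: inter-device lag bound
HEART_MAX_LAG_S = 0.4    # heart-body window: below the inter-segment spacing
MIN_TRIALS = 5


@dataclass
class XCorrResult:
    coefficient: float   # max |r| over the lag window, in [0, 1]
    lag_s: float         # signed; positive = first argument leads the second
    sign: int            # sign of r at the maximum


@dataclass
class AdjacencyMatrix:
    """Symmetric weights (max |xcorr|) and antisymmetric lags (seconds)."""

    labels: list[str]
    weights: np.ndarray
    lags: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.labels)
        if self.weights.shape != (k, k) or self.lags.shape != (k, k):
            raise ValueError("matrix shapes must match label count")


@dataclass
class NodeMetrics:
    labels: list[str]
    clustering: np.ndarray
    degree: np.ndarray
    triangle_intensity: np.ndarray


@dataclass
class HeartEdge:
    part: str
    coefficient: float
    lag_s: float
    emd: float
    n_trials: int


def _pick_max(r_abs: np.ndarray, lags: np.ndarray) -> int:
    """Index of the maximal |r|; ties resolve to the smallest |lag|, then
    to the positive lag (deterministic)."""
    best = r_abs.max()
    cand = np.flatnonzero(r_abs == best)
    order = np.lexsort((-np.sign(lags[cand]), np.abs(lags[cand])))
    return int(cand[order[0]])


def max_xcorr(
    x: np.ndarray, y: np.ndarray, rate: float, max_lag: float = MAX_LAG_S
) -> XCorrResult:
    """Maximal normalized cross-correlation between two equal-rate series.

    Both series are mean-centered and unit-scaled; the biased normalization
    (dividing by the full length rather than the overlap) tapers estimates
    at extreme lags, suppressing spurious short-overlap maxima.  Positive
    lag means ``x`` leads ``y`` (x's features occur earlier).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero-variance input: constant signal has no correlation structure")
    xc = (x - x.mean()) / sx
    yc = (y - y.mean()) / sy
    c = signal.correlate(yc, xc, mode="full", method="auto")
    lags = signal.correlation_lags(len(yc), len(xc), mode="full")
    n = max(len(x), len(y))
    r = c / n
    max_lag_samples = int(round(max_lag * rate))
    keep = np.abs(lags) <= max_lag_samples
    r, lags = r[keep], lags[keep]
    i = _pick_max(np.abs(r), lags.astype(float))
    return XCorrResult(float(abs(r[i])), float(lags[i] / rate), int(np.sign(r[i]) or 1))


def windowed_xcorr(
    x_full: np.ndarray,
    y_window: np.ndarray,
    window_start: int,
    rate: float,
    max_lag: float = MAX_LAG_S,
    signed: bool = False,
) -> XCorrResult:
    """Cross-correlate a fixed window of ``y`` against sliding windows of ``x``.

    ``y_window`` is compared with ``x_full[window_start + tau : ...]`` for
    every integer shift tau within the lag window; each x-window is centered
    and scaled individually, so the result is a proper normalized
    correlation at every lag.  The reported lag is positive when ``x``
    leads ``y``.

    With ``signed=True`` the maximal (signed) correlation is located rather
    than the maximal magnitude — appropriate when only a co-activation, not
    an inversion, is a meaningful match (heart envelope vs. speed).
    """
    x = np.asarray(x_full, dtype=float)
    y = np.asarray(y_window, dtype=float)
    L = len(y)
    m = int(round(max_lag * rate))
    lo = max(-m, -window_start)
    hi = min(m, len(x) - L - window_start)
    if hi < lo:
        raise ValueError("x series too short for the requested window")
    sy = y.std()
    if sy == 0.0:
        raise ValueError("zero-variance y window")
    yc = (y - y.mean()) / sy

    taus = np.arange(lo, hi + 1)
    views = np.lib.stride_tricks.sliding_window_view(x, L)[window_start + taus]
    vc = views - views.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(vc, axis=1)
    norms[norms == 0.0] = np.inf
    r = (vc @ yc) / (norms * np.sqrt(L))
    score = r if signed else np.abs(r)
    i = _pick_max(score, -taus.astype(float))
    # x shifted later (tau > 0) matching y means x's features come later: x lags
    return XCorrResult(float(abs(r[i])), float(-taus[i] / rate), int(np.sign(r[i]) or 1))


# ----------------------------------------------------------------------------
# body-body network
# ----------------------------------------------------------------------------

def build_adjacency(
    speeds: dict[str, np.ndarray],
    segmentation: TrialSegmentation,
    segment: str,
    rate: float,
    max_lag: float = MAX_LAG_S,
) -> AdjacencyMatrix:
    """Adjacency over body parts from per-segment speed cross-correlations.

    The requested segment's intervals from all valid trials are concatenated
    per part and a single normalized cross-correlation is taken per pair
    (pooling the segment's full sample rather than averaging short per-trial
    estimates, whose lag windows would exceed the interval length).
    """
    if segment not in ("forward", "backward"):
        raise ValueError("segment must be 'forward' or 'backward'")
    valid = segmentation.valid_trials
    if len(valid) < MIN_TRIALS:
        raise InsufficientDataError(
            f"need >= {MIN_TRIALS} valid trials, got {len(valid)}"
        )
    labels = list(speeds)
    slices = [getattr(t, segment) for t in valid]
    cut = {
        lab: np.concatenate([speeds[lab][a:b] for a, b in slices]) for lab in labels
    }
    k = len(labels)
    weights = np.zeros((k, k))
    lags = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = max_xcorr(cut[labels[i]], cut[labels[j]], rate, max_lag)
            weights[i, j] = weights[j, i] = res.coefficient
            lags[i, j] = res.lag_s
            lags[j, i] = -res.lag_s
    return AdjacencyMatrix(labels, weights, lags)


def clustering_coefficients(adj: AdjacencyMatrix) -> NodeMetrics:
    """Weighted clustering coefficients from geometric-mean triangle intensity.

    Edge weights are normalized by the maximum weight; t_i sums the cube
    roots of triangle weight products over unordered neighbor pairs, and
    C_i = 2 t_i / (k_i (k_i - 1)) with degree k_i counted over nonzero
    edges.  Nodes of degree < 2 have C_i = 0.
    """
    w = np.array(adj.weights, dtype=float)
    np.fill_diagonal(w, 0.0)
    wmax = w.max()
    k_deg = (w > 0).sum(axis=0)
    if wmax == 0.0:
        z = np.zeros(len(adj.labels))
        return NodeMetrics(adj.labels, z, k_deg, z.copy())
    w_hat = (w / wmax) ** (1.0 / 3.0)
    t = np.diag(w_hat @ w_hat @ w_hat) / 2.0  # unordered neighbor pairs
    denom = k_deg * (k_deg - 1)
    c = np.where(denom > 0, 2.0 * t / np.where(denom > 0, denom, 1), 0.0)
    return NodeMetrics(adj.labels, c, k_deg, t)


# ----------------------------------------------------------------------------
# heart-body network
# ----------------------------------------------------------------------------

def ecg_envelope(
    ecg: EcgRecording,
    qrs_mask_s: float = 0.10,
    smooth_s: float = 0.08,
) -> np.ndarray:
    """Amplitude envelope of the (filtered) ECG with beat-transient removal.

    QRS complexes are sparse, high-amplitude transients riding on the
    sustained in-band activity whose amplitude modulation carries the slow
    autonomic signal.  Beats are located on a high-passed copy of the
    analytic-signal magnitude (cardiac period from its autocorrelation, one
    maximum per cycle), masked for ``qrs_mask_s`` seconds on either side and
    bridged by band-limited inpainting; the remaining beat-locked residual
    (identical ringing tails) is removed by per-beat template subtraction,
    and the result is low-passed and smoothed with a Hann window.  All
    steps are symmetric in time and introduce no lag bias.
    """
    x = np.asarray(ecg.mv, dtype=float)
    env = np.abs(signal.hilbert(x))
    # beats are located on a high-passed copy of the envelope: removing the
    # slow (movement-locked) modulation leaves only the narrow beat spikes,
    # so neither the period search nor the peak picking can lock onto the
    # task rhythm
    sos_hp = signal.butter(4, 4.0, btype="highpass", fs=ecg.rate, output="sos")
    env_hp = signal.sosfiltfilt(sos_hp, env) if len(env) > 64 else env - env.mean()
    period = _beat_period_samples(env_hp, ecg.rate)
    if period is not None:
        peaks, _ = signal.find_peaks(env_hp, distance=max(2, int(0.7 * period)))
        spike_size = np.median(env_hp[peaks]) if len(peaks) else 0.0
        if len(peaks) and spike_size > 4.0 * np.median(np.abs(env_hp)):
            # first pass: mask the beats and bridge by band-limited
            # inpainting to get a provisional slow envelope
            half = int(round(qrs_mask_s * ecg.rate))
            mask = np.zeros(len(env), dtype=bool)
            for p in peaks:
                mask[max(0, p - half) : p + half + 1] = True
            if not mask.all():
                slow = _bandlimited_inpaint(env, mask, ecg.rate)
                # second pass: the beat-locked residual (identical beat
                # waveforms, including ringing tails beyond the mask) is
                # estimated as a per-beat median template and subtracted,
                # leaving no masking holes in the corrected envelope
                env = _subtract_beat_template(env, env - slow, peaks, int(period))
    m = int(round(smooth_s * ecg.rate)) | 1
    win = np.hanning(m)
    sos_lp = signal.butter(4, 3.0, fs=ecg.rate, output="sos")
    if len(env) > 64:
        env = signal.sosfiltfilt(sos_lp, env)
    return np.convolve(env, win / win.sum(), mode="same")


def _subtract_beat_template(
    env: np.ndarray, resid: np.ndarray, peaks: np.ndarray, period: int
) -> np.ndarray:
    half = period // 2
    windows = [
        resid[p - half : p + half + 1]
        for p in peaks
        if p - half >= 0 and p + half + 1 <= len(resid)
    ]
    if len(windows) < 3:
        return env
    template = np.median(np.stack(windows), axis=0)
    template -= np.linspace(template[0], template[-1], len(template))
    out = env.copy()
    for p in peaks:
        a, b = p - half, p + half + 1
        ta, tb = 0, len(template)
        if a < 0:
            ta, a = -a, 0
        if b > len(out):
            tb, b = len(template) - (b - len(out)), len(out)
        out[a:b] -= template[ta:tb]
    return out


def _bandlimited_inpaint(
    env: np.ndarray, mask: np.ndarray, rate: float,
    cutoff_hz: float = 3.0, n_iter: int = 20,
) -> np.ndarray:
    """Reconstruct masked stretches of a slow envelope by iterative
    low-pass projection: the slow amplitude modulation is band-limited well
    below the cardiac rate, so alternating between the low-pass constraint
    and the observed samples converges to a smooth, unbiased bridge."""
    idx = np.arange(len(env))
    filled = env.copy()
    filled[mask] = np.interp(idx[mask], idx[~mask], env[~mask])
    sos = signal.butter(4, cutoff_hz, fs=rate, output="sos")
    smooth = filled
    for _ in range(n_iter):
        smooth = signal.sosfiltfilt(sos, filled)
        filled = np.where(mask, smooth, env)
    return smooth


def _beat_period_samples(env: np.ndarray, rate: float) -> float | None:
    """Cardiac period from the autocorrelation of the amplitude envelope.

    Searches inter-beat intervals between 0.24 and 3 s (20-250 bpm);
    returns None when no clear periodicity exists.
    """
    lo, hi = int(0.24 * rate), min(int(3.0 * rate), len(env) // 2)
    if hi <= lo:
        return None
    e = env - env.mean()
    ac = signal.fftconvolve(e, e[::-1], mode="full")[len(e) - 1 :]
    if ac[0] <= 0:
        return None
    window = ac[lo:hi] / ac[0]
    k = int(np.argmax(window))
    if window[k] < 0.1:
        return None
    return float(lo + k)


def heart_body_connectivity(
    ecg_filtered: EcgRecording,
    speeds: dict[str, np.ndarray],
    segmentation: TrialSegmentation,
    segment: str,
    *,
    max_lag: float = HEART_MAX_LAG_S,
    part_hists: dict[str, Histogram] | None = None,
    ekg_hist: Histogram | None = None,
    envelope: np.ndarray | None = None,
) -> list[HeartEdge]:
    """Per-body-part heart edges: median cross-correlation, lead/lag, EMD.

    For every valid trial, the ECG amplitude envelope is cross-correlated
    with the part's linear-speed series over the requested segment interval;
    the per-trial maximal coefficient and its signed lag are collected and
    summarized by their medians (positive lag = the heart signal leads the
    kinematics).  If MMS histograms are supplied, the EMD between the
    part's and the heart's amplitude distributions is attached.

    Kinematics must already be resampled to the ECG rate, and the
    segmentation rescaled accordingly.
    """
    if not ecg_filtered.filtered:
        raise ValueError("pass the band-passed ECG (see bandpass_ecg)")
    if abs(segmentation.rate - ecg_filtered.rate) > 1e-9:
        raise RateMismatchError(
            "kinematics/segmentation must be resampled to the ECG rate"
        )
    valid = segmentation.valid_trials
    if len(valid) < MIN_TRIALS:
        raise InsufficientDataError(f"need >= {MIN_TRIALS} valid trials")
    env = ecg_envelope(ecg_filtered) if envelope is None else envelope
    rate = ecg_filtered.rate

    edges = []
    for part, speed in speeds.items():
        coefs, lags = [], []
        for t in valid:
            a, b = getattr(t, segment)
            b = min(b, len(speed))
            if b - a < 8:
                continue
            try:
                res = windowed_xcorr(env, speed[a:b], a, rate, max_lag, signed=True)
            except ValueError:
                continue
            coefs.append(res.coefficient)
            lags.append(res.lag_s)
        if not coefs:
            continue
        d = float("nan")
        if part_hists is not None and ekg_hist is not None and part in part_hists:
            d = emd(part_hists[part], ekg_hist)
        edges.append(
            HeartEdge(part, float(np.median(coefs)), float(np.median(lags)), d, len(coefs))
        )
    return edges
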
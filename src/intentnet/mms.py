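"""Micro-movement spikes (MMS): extraction and standardization.

A biorhythm waveform with peaks and valleys (here: angular-acceleration
magnitudes, pairwise absolute differences thereof, or rectified ECG) is
reduced to a unitless spike train.  Each local maximum ``p`` flanked by local
minima ``m1, m2`` contributes a standardized amplitude

    a = p / (p + (m1 + m2) / 2)

which lies in the real-valued interval [0, 1].  The standardization is
invariant under positive rescaling of the waveform, which is what makes
amplitudes comparable across sensors with different physical units and across
participants of different anatomical size (allometric normalization).  For a
nonnegative waveform the flanking minima are below the peak, so amplitudes in
fact concentrate in (1/2, 1]; treating them as a continuous random process
and fitting a Gamma family is the job of :mod:`intentnet.stochastic`.

Spike trains come in two modes: ``amplitude_only`` (just the amplitudes) and
``frame_preserving`` (a full-length waveform with zeros at non-spike frames).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .stochastic import Histogram

__all__ = [
    "MmsTrain",
    "find_peaks_valleys",
    "standardize_peaks",
    "pairwise_absdiff",
    "mms_histogram",
]

#: minimum number of spike amplitudes required before histogramming/fitting
MIN_SPIKE_COUNT = 100


@dataclass
class MmsTrain:
    """Standardized micro-movement spike train.

    Attributes
    ----------
    indices : ndarray of int
        Frame index of each retained spike (strictly increasing).
    amplitudes : ndarray
        Standardized amplitudes, all in [0, 1].
    source_length : int
        Length of the waveform the spikes came from.
    mode : str
        ``"amplitude_only"`` or ``"frame_preserving"``.
    n_dropped : int
        Peaks discarded because the 0/0 standardization was undefined.
    """

    indices: np.ndarray
    amplitudes: np.ndarray
    source_length: int
    mode: str = "amplitude_only"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if len(self.indices) != len(self.amplitudes):
            raise ValueError("indices and amplitudes must align")
        if len(self.indices) > 1 and np.any(np.diff(self.indices) <= 0):
            raise ValueError("spike indices must be strictly increasing")

    def padded(self) -> np.ndarray:
        """Frame-preserving representation: zeros at non-spike frames."""
        out = np.zeros(self.source_length)
        out[self.indices] = self.amplitudes
        return out

    def __len__(self) -> int:
        return len(self.amplitudes)


def _compress_plateaus(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse runs of equal consecutive values to their midpoint sample.

    Returns (representative indices, run values).  Plateau extrema thereby
    resolve deterministically to the plateau midpoint.
    """
    change = np.empty(len(series), dtype=bool)
    change[0] = True
    change[1:] = series[1:] != series[:-1]
    starts = np.flatnonzero(change)
    ends = np.append(starts[1:], len(series))  # exclusive
    reps = (starts + ends - 1) // 2
    return reps, series[starts]


def find_peaks_valleys(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strict local maxima and minima of a scalar series, with alternation.

    Plateaus collapse to their midpoint sample; leading/trailing samples are
    never extrema.  Because extrema are sign changes of the (plateau-free)
    first difference, maxima and minima alternate by construction: between
    two retained minima lies exactly one maximum.

    Returns ``(maxima_indices, minima_indices)``.  A constant series yields
    two empty arrays.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if len(x) < 3:
        raise ValueError("series must have length >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")

    reps, vals = _compress_plateaus(x)
    if len(vals) < 3:
        empty = np.array([], dtype=int)
        return empty, empty
    rising = vals[1:] > vals[:-1]  # strict by construction of runs
    is_max = rising[:-1] & ~rising[1:]
    is_min = ~rising[:-1] & rising[1:]
    interior = reps[1:-1]
    return interior[is_max], interior[is_min]


def standardize_peaks(series: np.ndarray, mode: str = "amplitude_only") -> MmsTrain:
    """Standardize each peak by itself plus the mean of its flanking minima.

    The input must be nonnegative (use magnitudes or absolute differences).
    Peaks lacking a flanking minimum on either side (the first or last
    extremum of the alternating sequence when it is a maximum) carry no
    well-defined amplitude and are excluded, as are degenerate 0/0 peaks.
    """
    x = np.asarray(series, dtype=float)
    if np.any(x < 0):
        raise ValueError("series must be nonnegative; pass magnitudes")
    if mode not in ("amplitude_only", "frame_preserving"):
        raise ValueError(f"unknown mode {mode!r}")
    maxima, minima = find_peaks_valleys(x)
    if len(maxima) == 0 or len(minima) < 2:
        return MmsTrain(np.array([], int), np.array([]), len(x), mode)

    # flanking minima: positions of each maximum within the minima sequence
    right = np.searchsorted(minima, maxima)
    keep = (right > 0) & (right < len(minima))
    m_idx = maxima[keep]
    left_min = x[minima[right[keep] - 1]]
    right_min = x[minima[right[keep]]]
    peaks = x[m_idx]
    denom = peaks + 0.5 * (left_min + right_min)
    ok = denom > 0.0
    amplitudes = peaks[ok] / denom[ok]
    return MmsTrain(m_idx[ok], amplitudes, len(x), mode, n_dropped=int(np.sum(~ok)))


def pairwise_absdiff(series_a: np.ndarray, series_b: np.ndarray) -> np.ndarray:
    """Elementwise |a - b| of two equally long series sharing a rate.

    The absolute difference of two body parts' angular-acceleration waveforms
    reflects the change in positional relation between them; its MMS quantify
    the stochasticity of that pairwise connectivity.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return np.abs(a - b)


def mms_histogram(amplitudes: np.ndarray, min_spike_count: int = MIN_SPIKE_COUNT) -> Histogram:
    """Frequency histogram of MMS amplitudes with Freedman-Diaconis binning.

    Bin width 2*IQR*n^(-1/3); bins cover [min, max]; weights normalized to
    sum to one.  When the IQR is zero the square-root rule is used instead
    (with a warning); identical values collapse to a single bin.
    """
    a = np.sort(np.asarray(amplitudes, dtype=float))
    n = len(a)
    if n < min_spike_count:
        from .errors import InsufficientDataError

        raise InsufficientDataError(f"need >= {min_spike_count} amplitudes, got {n}")
    lo, hi = a[0], a[-1]
    if hi == lo:
        width = max(abs(lo), 1.0) * 1e-6
        return Histogram(np.array([lo - width, lo + width]), np.array([1.0]))
    q75, q25 = np.percentile(a, [75, 25])
    iqr = q75 - q25
    if iqr > 0:
        bw = 2.0 * iqr * n ** (-1.0 / 3.0)
    else:
        warnings.warn("IQR is zero; falling back to square-root binning rule")
        bw = (hi - lo) / np.sqrt(n)
    n_bins = max(1, int(np.ceil((hi - lo) / bw)))
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, edges = np.histogram(a, bins=edges)
    weights = counts / counts.sum()
    return Histogram(edges, weights)
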
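"""End-to-end session analysis: glue over the analysis modules.

Order of operations for one participant's session:

1. segment trials from the end effector's speed and distance-to-target
   (240 Hz), flag noisy trials;
2. per body part, derive angular-acceleration magnitudes, slice per
   segment, extract and pool MMS amplitudes, fit the Gamma law (NSR);
   likewise for every pair's absolute-difference waveform;
3. build the per-segment cross-correlation adjacency over linear speeds and
   compute weighted clustering coefficients;
4. band-pass the ECG, extract its MMS and amplitude envelope, resample the
   kinematics to the ECG rate, and attach per-part heart edges (median
   cross-correlation, signed lead/lag, EMD between amplitude histograms);
5. aggregate everything into per-(segment x side) cells and deltas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import compare
from .errors import InsufficientDataError
from .kinematics import angular_acceleration, angular_speed_from_quaternions, linear_speed
from .mms import mms_histogram, pairwise_absdiff, standardize_peaks
from .network import (
    AdjacencyMatrix,
    HeartEdge,
    NodeMetrics,
    build_adjacency,
    clustering_coefficients,
    ecg_envelope,
    heart_body_connectivity,
)
from .preprocessing import (
    EcgRecording,
    KinematicsRecording,
    TrialSegmentation,
    bandpass_ecg,
    flag_noisy_trials,
    resample_kinematics,
    segment_trials,
    target_distance_series,
)
from .stochastic import GammaFit, Histogram, fit_gamma_mle
from .synthetic import SessionConfig, SessionData, generate_session

__all__ = ["AnalysisParams", "SessionMetrics", "analyze_session", "run_cohort"]

SEGMENTS = ("forward", "backward")


@dataclass
class AnalysisParams:
    """Tunable analysis thresholds (defaults mirror the study's rules)."""

    speed_threshold_frac: float = 0.05
    touch_radius_m: float = 0.02
    max_pos_jump_m: float = 0.10
    max_lag_s: float = 1.0
    heart_max_lag_s: float = 0.4
    min_spike_count: int = 100
    min_trials: int = 5
    ecg_band: tuple[float, float] = (5.0, 30.0)
    ecg_filter_order: int = 2
    min_slice_frames: int = 8
    envelope_qrs_mask_s: float = 0.10
    envelope_smooth_s: float = 0.08


@dataclass
class SessionMetrics:
    """Everything measured on one session."""

    participant: str
    handedness: str
    side_map: dict[str, str]
    segmentation: TrialSegmentation
    nsr_aa: dict[tuple[str, str], GammaFit]
    nsr_aa_diff: dict[tuple[tuple[str, str], str], GammaFit]
    adjacency: dict[str, AdjacencyMatrix]
    nodes: dict[str, NodeMetrics]
    heart: dict[str, list[HeartEdge]]
    mms_hists: dict[tuple[str, str], Histogram] = field(default_factory=dict)
    ekg_hists: dict[str, Histogram] = field(default_factory=dict)

    @property
    def n_valid_trials(self) -> int:
        return len(self.segmentation.valid_trials)


def _pooled_amplitudes(
    series: np.ndarray, slices: list[tuple[int, int]], min_frames: int
) -> np.ndarray:
    out = []
    for a, b in slices:
        b = min(b, len(series))
        if b - a >= min_frames:
            out.append(standardize_peaks(series[a:b]).amplitudes)
    return np.concatenate(out) if out else np.array([])


def analyze_session(
    kin: KinematicsRecording,
    ecg: EcgRecording,
    trials,
    handedness: str,
    params: AnalysisParams | None = None,
    participant: str = "p0",
) -> SessionMetrics:
    """Run the full analysis on one session.

    ``trials`` is the session's trial table (columns trial_id,
    window_start, window_end, target_x/y/z) giving per-trial windows and
    target positions; segmentation itself comes from the speed/distance
    criteria.
    """
    p = params or AnalysisParams()
    labels = list(kin.parts)
    side_map = compare.assign_sides(labels, handedness)
    ee = next(
        lab for lab in labels
        if lab.endswith("_index") or lab.endswith("_finger")
    )

    # ---- 1. segmentation on the native kinematics rate
    ee_speed = linear_speed(kin.parts[ee].pos, kin.rate).values
    windows = list(zip(trials["window_start"].astype(int), trials["window_end"].astype(int)))
    targets = np.column_stack(
        [trials["target_x"], trials["target_y"], trials["target_z"]]
    )
    distance = target_distance_series(kin.parts[ee].pos, windows, targets)
    seg = segment_trials(
        ee_speed,
        distance,
        p.speed_threshold_frac,
        trial_windows=windows,
        touch_radius=p.touch_radius_m,
        rate=kin.rate,
    )
    seg = flag_noisy_trials(kin, seg, p.max_pos_jump_m)
    valid = seg.valid_trials
    if len(valid) < p.min_trials:
        raise InsufficientDataError(f"only {len(valid)} valid trials")
    slices = {s: [getattr(t, s) for t in valid] for s in SEGMENTS}

    # ---- 2. spatial domain: MMS of |angular acceleration| and pair diffs
    aa = {
        lab: np.abs(
            angular_acceleration(
                angular_speed_from_quaternions(kin.parts[lab].quat, kin.rate, lab)
            ).values
        )
        for lab in labels
    }
    nsr_aa: dict[tuple[str, str], GammaFit] = {}
    mms_hists: dict[tuple[str, str], Histogram] = {}
    for lab in labels:
        for s in SEGMENTS:
            amps = _pooled_amplitudes(aa[lab], slices[s], p.min_slice_frames)
            if len(amps) >= p.min_spike_count:
                nsr_aa[(lab, s)] = fit_gamma_mle(amps, p.min_spike_count)
                mms_hists[(lab, s)] = mms_histogram(amps, p.min_spike_count)

    nsr_aa_diff: dict[tuple[tuple[str, str], str], GammaFit] = {}
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            diff = pairwise_absdiff(aa[la], aa[lb])
            for s in SEGMENTS:
                amps = _pooled_amplitudes(diff, slices[s], p.min_slice_frames)
                if len(amps) >= p.min_spike_count:
                    nsr_aa_diff[((la, lb), s)] = fit_gamma_mle(amps, p.min_spike_count)

    # ---- 3. temporal domain: speed cross-correlation network
    speeds = {lab: linear_speed(kin.parts[lab].pos, kin.rate, lab).values for lab in labels}
    adjacency, nodes = {}, {}
    for s in SEGMENTS:
        adjacency[s] = build_adjacency(speeds, seg, s, kin.rate, p.max_lag_s)
        nodes[s] = clustering_coefficients(adjacency[s])

    # ---- 4. heart-kinematics network
    ecg_f = bandpass_ecg(ecg, *p.ecg_band, order=p.ecg_filter_order)
    seg256 = seg.at_rate(ecg_f.rate)
    slices256 = {s: [getattr(t, s) for t in seg256.valid_trials] for s in SEGMENTS}
    ekg_abs = np.abs(ecg_f.mv)
    ekg_hists: dict[str, Histogram] = {}
    for s in SEGMENTS:
        amps = _pooled_amplitudes(ekg_abs, slices256[s], p.min_slice_frames)
        if len(amps) >= p.min_spike_count:
            ekg_hists[s] = mms_histogram(amps, p.min_spike_count)

    kin256 = resample_kinematics(kin, ecg_f.rate)
    speeds256 = {
        lab: linear_speed(kin256.parts[lab].pos, ecg_f.rate, lab).values for lab in labels
    }
    env = ecg_envelope(
        ecg_f, qrs_mask_s=p.envelope_qrs_mask_s, smooth_s=p.envelope_smooth_s
    )
    heart: dict[str, list[HeartEdge]] = {}
    for s in SEGMENTS:
        part_hists = {
            lab: mms_hists[(lab, s)] for lab in labels if (lab, s) in mms_hists
        }
        heart[s] = heart_body_connectivity(
            ecg_f,
            speeds256,
            seg256,
            s,
            max_lag=p.heart_max_lag_s,
            part_hists=part_hists,
            ekg_hist=ekg_hists.get(s),
            envelope=env,
        )

    return SessionMetrics(
        participant, handedness, side_map, seg,
        nsr_aa, nsr_aa_diff, adjacency, nodes, heart, mms_hists, ekg_hists,
    )


# ----------------------------------------------------------------------------
# aggregation into segment x side cells
# ----------------------------------------------------------------------------

def _edge_side(side_a: str, side_b: str) -> str:
    if side_a == side_b and side_a in ("performing", "non_performing"):
        return side_a
    return "mixed"


def comparison_from_metrics(sm: SessionMetrics) -> compare.IntentComparison:
    """Build the per-participant cell/delta structure from session metrics."""
    side = sm.side_map
    mv: dict[str, dict[tuple[str, str], list[float]]] = {m: {} for m in compare.METRICS}

    def push(metric: str, seg: str, sd: str, value: float) -> None:
        mv[metric].setdefault((seg, sd), []).append(float(value))

    for (lab, s), fit in sm.nsr_aa.items():
        push("nsr_aa", s, side[lab], fit.nsr)
    for ((la, lb), s), fit in sm.nsr_aa_diff.items():
        push("nsr_aa_diff", s, _edge_side(side[la], side[lb]), fit.nsr)
    for s in SEGMENTS:
        adj = sm.adjacency[s]
        k = len(adj.labels)
        for i in range(k):
            for j in range(i + 1, k):
                push("xcorr", s, _edge_side(side[adj.labels[i]], side[adj.labels[j]]),
                     adj.weights[i, j])
        nm = sm.nodes[s]
        for lab, c in zip(nm.labels, nm.clustering):
            push("cc", s, side[lab], c)
        for e in sm.heart[s]:
            if np.isfinite(e.emd):
                push("emd", s, side[e.part], e.emd)
            push("heart_xcorr", s, side[e.part], e.coefficient)
            push("heart_lag", s, side[e.part], e.lag_s)

    counts = {
        "valid_trials": sm.n_valid_trials,
        "nsr_aa_cells": len(sm.nsr_aa),
        "nsr_aa_diff_cells": len(sm.nsr_aa_diff),
    }
    return compare.aggregate(mv, sm.participant, counts)


def run_cohort(
    configs: list[SessionConfig],
    params: AnalysisParams | None = None,
) -> tuple[list[SessionMetrics], list[compare.IntentComparison], compare.ConsistencySummary]:
    """Generate and analyze a synthetic cohort, one config per participant."""
    metrics, comps = [], []
    for i, cfg in enumerate(configs):
        session = generate_session(cfg)
        sm = analyze_session(
            session.kinematics, session.ecg, session.trials, cfg.handedness,
            params, participant=f"p{i}",
        )
        metrics.append(sm)
        comps.append(comparison_from_metrics(sm))
    summary = compare.summarize(comps)
    return metrics, comps, summary
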
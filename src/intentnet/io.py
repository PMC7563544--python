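"""Reading and writing the session CSV schema and result JSON files.

A session on disk is a directory with:

* ``kinematics.csv`` — long format: time_s, sensor_id, x_m, y_m, z_m,
  qw, qx, qy, qz (scalar-first quaternions);
* ``ecg.csv`` — time_s, mv;
* ``trials.csv`` — trial_id, window_start, window_end (half-open, 0-based
  frames at the kinematics rate), target_x/y/z (m);
* ``ground_truth.json`` (optional) — the generator's injected truth;
* ``config.yaml`` (optional) — the generating configuration.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compare import ConsistencySummary, IntentComparison, format_summary
from .preprocessing import EcgRecording, KinematicsRecording, SensorTrack
from .synthetic import GroundTruth, SegmentEvent, SessionConfig, SessionData

__all__ = [
    "write_session",
    "read_session",
    "config_to_yaml",
    "config_from_yaml",
    "write_comparison",
    "write_summary",
]


def _cellkey(key: tuple[str, str]) -> str:
    return f"{key[0]}.{key[1]}"


def config_to_yaml(config: SessionConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["body_parts"] = [
        {"label": p.label, "side": p.side, "is_end_effector": p.is_end_effector}
        for p in config.body_parts
    ]
    d["gamma_params"] = {_cellkey(k): list(v) for k, v in config.gamma_params.items()}
    if isinstance(config.coupling, dict):
        d["coupling"] = {_cellkey(k): v for k, v in config.coupling.items()}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def config_from_yaml(path: str | Path) -> SessionConfig:
    from .synthetic import BodyPart

    d = yaml.safe_load(Path(path).read_text())
    if "body_parts" in d and d["body_parts"] is not None:
        d["body_parts"] = tuple(BodyPart(**p) for p in d["body_parts"])
    if "gamma_params" in d:
        d["gamma_params"] = {
            tuple(k.split(".")): tuple(v) for k, v in d["gamma_params"].items()
        }
    if isinstance(d.get("coupling"), dict):
        d["coupling"] = {tuple(k.split(".")): v for k, v in d["coupling"].items()}
    return SessionConfig(**d)


def write_session(session: SessionData, outdir: str | Path) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    kin = session.kinematics
    frames = []
    times = kin.times
    for label, tr in kin.parts.items():
        df = pd.DataFrame(
            {
                "time_s": times,
                "sensor_id": label,
                "x_m": tr.pos[:, 0], "y_m": tr.pos[:, 1], "z_m": tr.pos[:, 2],
                "qw": tr.quat[:, 0], "qx": tr.quat[:, 1],
                "qy": tr.quat[:, 2], "qz": tr.quat[:, 3],
            }
        )
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(out / "kinematics.csv", index=False)
    pd.DataFrame({"time_s": session.ecg.times, "mv": session.ecg.mv}).to_csv(
        out / "ecg.csv", index=False
    )
    session.trials.to_csv(out / "trials.csv", index=False)

    gt = session.ground_truth
    gt_json = {
        "forward_intervals": [list(map(int, x)) for x in gt.forward_intervals],
        "backward_intervals": [list(map(int, x)) for x in gt.backward_intervals],
        "trial_windows": [list(map(int, x)) for x in gt.trial_windows],
        "targets": np.asarray(gt.targets).tolist(),
        "gamma_params": {_cellkey(k): list(v) for k, v in gt.gamma_params.items()},
        "heart_lead_ms": gt.heart_lead_ms,
        "anticipation_ms": gt.anticipation_ms,
        "clock_offset_s": gt.clock_offset_s,
        "events": [
            {"t_peak_s": e.t_peak_s, "segment": e.segment, "duration_s": e.duration_s}
            for e in gt.events
        ],
    }
    (out / "ground_truth.json").write_text(json.dumps(gt_json))
    config_to_yaml(session.config, out / "config.yaml")
    return out


def read_session(
    indir: str | Path,
) -> tuple[KinematicsRecording, EcgRecording, pd.DataFrame, GroundTruth | None]:
    indir = Path(indir)
    kdf = pd.read_csv(indir / "kinematics.csv")
    parts = {}
    rate = None
    for label, g in kdf.groupby("sensor_id", sort=False):
        g = g.sort_values("time_s")
        if rate is None:
            dt = np.diff(g["time_s"].to_numpy())
            rate = 1.0 / np.median(dt)
        parts[str(label)] = SensorTrack(
            g[["x_m", "y_m", "z_m"]].to_numpy(),
            g[["qw", "qx", "qy", "qz"]].to_numpy(),
        )
    kin = KinematicsRecording(float(round(rate)), parts)

    edf = pd.read_csv(indir / "ecg.csv")
    et = edf["time_s"].to_numpy()
    ecg_rate = 1.0 / np.median(np.diff(et))
    ecg = EcgRecording(float(round(ecg_rate)), edf["mv"].to_numpy(), t0=float(et[0]))

    trials = pd.read_csv(indir / "trials.csv")

    gt = None
    gt_path = indir / "ground_truth.json"
    if gt_path.exists():
        d = json.loads(gt_path.read_text())
        gt = GroundTruth(
            [tuple(x) for x in d["forward_intervals"]],
            [tuple(x) for x in d["backward_intervals"]],
            [tuple(x) for x in d["trial_windows"]],
            np.asarray(d["targets"]),
            {tuple(k.split(".")): tuple(v) for k, v in d["gamma_params"].items()},
            d["heart_lead_ms"],
            d["anticipation_ms"],
            d["clock_offset_s"],
            [SegmentEvent(**e) for e in d["events"]],
        )
    return kin, ecg, trials, gt


def write_comparison(comp: IntentComparison, path: str | Path) -> None:
    d = {
        "participant": comp.participant,
        "cells": {
            m: {_cellkey(k): v for k, v in cells.items()}
            for m, cells in comp.cells.items()
        },
        "deltas": comp.deltas,
        "counts": comp.counts,
    }
    Path(path).write_text(json.dumps(d, indent=1, allow_nan=True))


def write_summary(summary: ConsistencySummary, path: str | Path) -> None:
    d = {
        "n_participants": summary.n_participants,
        "symbols": {
            f"{m}:{c}": {"symbol": s, "favored": f}
            for (m, c), (s, f) in summary.symbols.items()
        },
        "lead": {cell: {"leader": lead, "symbol": s} for cell, (lead, s) in summary.lead.items()},
        "deltas": {f"{m}:{c}": v for (m, c), v in summary.deltas.items()},
    }
    p = Path(path)
    p.write_text(json.dumps(d, indent=1))
    p.with_suffix(".txt").write_text(format_summary(summary) + "\n")
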
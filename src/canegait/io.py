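"""Delimited-text and JSON I/O for every stream and report format.

All on-disk formats are plain text so recordings stay diffable: CSV for the
time series (one named column per channel, first column ``time_s``) and JSON
for ground truth and run reports.  Writing then reading any stream
reproduces it to representation precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import HandleLayout, N_SENSORS
from .segmentation import PHASES, KinematicsSeries, PhaseTimeline
from .simulate import CaneRecording, GroundTruth
from .variables import FSRSeries

_FSR_COLUMNS = [f"f{i:02d}" for i in range(1, N_SENSORS + 1)]
_KIN_COLUMNS = [
    "tracked_foot_speed",
    "opposite_foot_speed",
    "tracked_foot_angle",
    "tibia_angle",
    "feet_distance",
    "cane_angle",
]


class FormatError(ValueError):
    """Malformed input file (bad header, ragged rows, wrong column count)."""


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:
        raise FormatError(f"{path}: {e}") from e
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


# --- handle layout ---------------------------------------------------------


def write_layout(layout: HandleLayout, path: str | Path) -> None:
    layout.to_frame().to_csv(path, index=False)


def read_layout(path: str | Path) -> HandleLayout:
    df = _read_csv(path, ["sensor_id", "x_mm", "z_mm", "side"])
    try:
        return HandleLayout.from_frame(df)
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e


# --- cane stream -----------------------------------------------------------


def write_cane_recording(rec: CaneRecording, path: str | Path) -> None:
    df = pd.DataFrame(rec.fsr.forces, columns=_FSR_COLUMNS)
    df.insert(0, "time_s", rec.fsr.timestamps)
    df["cane_angle"] = rec.cane_angle
    df.to_csv(path, index=False, float_format="%.9g")


def read_fsr(path: str | Path) -> FSRSeries:
    """Read only the FSR channels of a cane-stream file."""
    df = _read_csv(path, ["time_s"] + _FSR_COLUMNS)
    try:
        return FSRSeries(
            timestamps=df["time_s"].to_numpy(),
            forces=df[_FSR_COLUMNS].to_numpy(),
        )
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e


def read_cane_recording(path: str | Path) -> CaneRecording:
    df = _read_csv(path, ["time_s", "cane_angle"] + _FSR_COLUMNS)
    try:
        return CaneRecording(
            fsr=FSRSeries(
                timestamps=df["time_s"].to_numpy(),
                forces=df[_FSR_COLUMNS].to_numpy(),
            ),
            cane_angle=df["cane_angle"].to_numpy(),
        )
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e


# --- kinematics stream -----------------------------------------------------


def write_kinematics(kin: KinematicsSeries, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": kin.timestamps})
    for c in _KIN_COLUMNS:
        df[c] = getattr(kin, c)
    df.to_csv(path, index=False, float_format="%.9g")


def read_kinematics(path: str | Path) -> KinematicsSeries:
    df = _read_csv(path, ["time_s"] + _KIN_COLUMNS)
    try:
        return KinematicsSeries(
            timestamps=df["time_s"].to_numpy(),
            **{c: df[c].to_numpy() for c in _KIN_COLUMNS},
        )
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e


# --- phase timeline ---------------------------------------------------------


def write_timeline(tl: PhaseTimeline, path: str | Path) -> None:
    df = pd.DataFrame(tl.strides)[list(PHASES)]
    df.insert(0, "stride_id", np.arange(tl.n_strides))
    df.to_csv(path, index=False, float_format="%.9g")


def read_timeline(path: str | Path, recording_end: float | None = None) -> PhaseTimeline:
    df = _read_csv(path, list(PHASES))
    strides = [
        {p: float(row[p]) for p in PHASES} for _, row in df.iterrows()
    ]
    return PhaseTimeline(strides=strides, recording_end=recording_end)


# --- ground truth -----------------------------------------------------------


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    payload = {
        "lag_s": gt.lag,
        "recording_end_s": gt.timeline.recording_end,
        "strides": gt.timeline.strides,
        "event_times": {
            f"{ch}:{kind}": times.tolist()
            for (ch, kind), times in gt.event_times.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    timeline = PhaseTimeline(
        strides=[{p: float(s[p]) for p in PHASES} for s in payload["strides"]],
        recording_end=payload.get("recording_end_s"),
    )
    event_times = {}
    for key, times in payload.get("event_times", {}).items():
        ch, kind = key.rsplit(":", 1)
        event_times[(ch, kind)] = np.asarray(times, dtype=float)
    return GroundTruth(
        timeline=timeline, lag=float(payload["lag_s"]), event_times=event_times
    )
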
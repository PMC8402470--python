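"""End-to-end pipeline: synchronize, smooth, segment, detect, consolidate.

The processing order mirrors the acquisition workflow: the two streams are
first aligned on the cane-inclination pair, the grip variables are computed
and Savitzky-Golay smoothed (derivatives taken after smoothing), the
reference kinematics are segmented into per-stride phase onsets, the central
strides are selected, and per-stride extrema of the 12 signals are detected
and consolidated into stride-consistent events.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .events import (
    DEFAULT_EXCLUDED_PHASES,
    DEFAULT_MIN_STRIDES,
    DEFAULT_N_CENTRAL,
    DEFAULT_PROMINENCE_FRACTION,
    DEFAULT_SG_WINDOW,
    EventSummary,
    NormalizedStrides,
    consolidate_events,
    detect_stride_extrema,
    normalize_stride_time,
    select_central_strides,
    smooth,
)
from .layout import HandleLayout, load_default_layout
from .segmentation import (
    KinematicsSeries,
    PhaseTimeline,
    SegmentationConfig,
    segment_gait,
)
from .simulate import CaneRecording, GaitSimConfig, simulate
from .sync import SyncResult, synchronize
from .variables import DerivedSeries, compute_derived, differentiate

logger = logging.getLogger("canegait")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is attached to the message."""


@dataclass
class PipelineConfig:
    """Everything one run needs.

    Either ``sim`` is set (simulate mode) or the three file paths are set
    (file mode).  The remaining fields parameterize the stages; every value
    used is echoed in the run report.
    """

    sim: GaitSimConfig | None = None
    layout_path: str | None = None
    cane_path: str | None = None
    kinematics_path: str | None = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    sync_max_lag: float = 5.0
    sg_window: int = DEFAULT_SG_WINDOW
    n_central_strides: int = DEFAULT_N_CENTRAL
    min_strides: int = DEFAULT_MIN_STRIDES
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION
    excluded_phases: tuple[str, ...] = DEFAULT_EXCLUDED_PHASES
    output_dir: str | None = None

    def __post_init__(self):
        if self.sim is None:
            missing = [
                n
                for n in ("cane_path", "kinematics_path")
                if getattr(self, n) is None
            ]
            if missing:
                raise ValueError(
                    f"file mode requires {missing}; or set sim for simulate mode"
                )
            for n in ("layout_path", "cane_path", "kinematics_path"):
                p = getattr(self, n)
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"{n}: {p} does not exist")
        if self.min_strides > self.n_central_strides:
            raise ValueError("min_strides cannot exceed n_central_strides")


@dataclass
class RunReport:
    """Everything a run produced, ready for serialization."""

    sync: SyncResult
    timeline: PhaseTimeline
    central_timeline: PhaseTimeline
    derived: DerivedSeries
    events: list[EventSummary]
    normalized: NormalizedStrides
    parameters: dict

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variable": e.variable,
                    "kind": e.kind,
                    "phase": e.phase,
                    "n_strides": e.n_strides_detected,
                    "total_strides": e.total_strides,
                    "median_offset_s": e.median_offset,
                    "iqr_s": e.iqr,
                }
                for e in self.events
            ]
        )

    def to_json_dict(self) -> dict:
        return {
            "parameters": self.parameters,
            "sync": {
                "lag_s": self.sync.lag,
                "peak_correlation": self.sync.peak_correlation,
                "resampled_length": self.sync.resampled_length,
            },
            "n_strides_segmented": self.timeline.n_strides,
            "n_strides_analyzed": self.central_timeline.n_strides,
            "events": [
                {
                    "variable": e.variable,
                    "kind": e.kind,
                    "phase": e.phase,
                    "n_strides_detected": e.n_strides_detected,
                    "total_strides": e.total_strides,
                    "median_offset_s": e.median_offset,
                    "iqr_s": e.iqr,
                    "offsets_s": e.offsets.tolist(),
                }
                for e in self.events
            ],
        }


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"[{name}] {exc}") from exc

    return _Ctx()


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Run the full analysis and optionally write the report files.

    Returns the :class:`RunReport`; if ``cfg.output_dir`` is set, also
    writes ``report.json``, ``events.tsv`` and ``timeline.csv`` there.
    """
    with _stage("load"):
        if cfg.sim is not None:
            layout = (
                cio.read_layout(cfg.layout_path)
                if cfg.layout_path
                else load_default_layout()
            )
            rec, kin, _truth = simulate(cfg.sim, layout)
        else:
            layout = (
                cio.read_layout(cfg.layout_path)
                if cfg.layout_path
                else load_default_layout()
            )
            rec = cio.read_cane_recording(cfg.cane_path)
            kin = cio.read_kinematics(cfg.kinematics_path)

    with _stage("synchronize"):
        sync = synchronize(
            rec.fsr.timestamps,
            rec.cane_angle,
            kin.timestamps,
            kin.cane_angle,
            max_lag=cfg.sync_max_lag,
        )
        logger.info("lag = %.4f s (r = %.4f)", sync.lag, sync.peak_correlation)
        fsr = dataclasses.replace(
            rec.fsr, timestamps=rec.fsr.timestamps + sync.lag
        )

    with _stage("derive"):
        derived = compute_derived(fsr, layout)
        derived = smooth(derived, window=cfg.sg_window)
        derived = differentiate(derived)

    with _stage("segment"):
        timeline = segment_gait(kin, cfg.segmentation)

    with _stage("central-strides"):
        central = select_central_strides(timeline, cfg.n_central_strides)

    with _stage("events"):
        cands = detect_stride_extrema(
            derived,
            central,
            prominence_fraction=cfg.prominence_fraction,
            excluded_phases=cfg.excluded_phases,
        )
        events = consolidate_events(
            cands,
            min_strides=cfg.min_strides,
            total_strides=cfg.n_central_strides,
        )
        normalized = normalize_stride_time(derived, central)

    parameters = {
        "mode": "simulate" if cfg.sim is not None else "file",
        "segmentation": dataclasses.asdict(cfg.segmentation),
        "sync_max_lag_s": cfg.sync_max_lag,
        "sg_window": cfg.sg_window,
        "sg_polyorder": 3,
        "n_central_strides": cfg.n_central_strides,
        "min_strides": cfg.min_strides,
        "prominence_fraction": cfg.prominence_fraction,
        "excluded_phases": list(cfg.excluded_phases),
    }
    if cfg.sim is not None:
        sim_dict = dataclasses.asdict(cfg.sim)
        sim_dict["planted_events"] = [
            dataclasses.asdict(e) for e in cfg.sim.planted_events
        ]
        parameters["sim"] = sim_dict
    for key, value in parameters.items():
        logger.info("parameter %s = %r", key, value)

    report = RunReport(
        sync=sync,
        timeline=timeline,
        central_timeline=central,
        derived=derived,
        events=events,
        normalized=normalized,
        parameters=parameters,
    )

    if cfg.output_dir is not None:
        with _stage("write"):
            out = Path(cfg.output_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / "report.json").write_text(
                json.dumps(report.to_json_dict(), indent=1)
            )
            report.events_frame().to_csv(out / "events.tsv", sep="\t", index=False)
            cio.write_timeline(central, out / "timeline.csv")
    return report
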
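"""Gait-event extraction from the synchronized grip-variable series.

After synchronization the derived grip variables are smoothed with a
3rd-order Savitzky-Golay filter, differentiated, and sliced by the reference
phase timeline.  Only the central strides of a recording are analyzed, to
avoid gait initiation/termination transients.  Per stride, local maxima and
minima of each of the 12 signals (6 variables + their ``d`` derivatives) are
detected and referenced to the nearest phase onset: the signed offset is the
event time minus the onset time, so negative offsets mean the event
*anticipates* the phase.  An event is reported only if it recurs in at least
``min_strides`` of the analyzed strides (default 25 of 30).

``terminal_stance`` is excluded as a reference phase by default: it sits so
close to pre-swing that events between the two cannot be resolved, and its
detection from kinematics is the least reliable of the seven onsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .segmentation import PHASES, PhaseTimeline
from .variables import DerivedSeries, InsufficientDataError, _interpolate_invalid

DEFAULT_SG_WINDOW = 11
SG_POLYORDER = 3
DEFAULT_N_CENTRAL = 30
DEFAULT_MIN_STRIDES = 25
DEFAULT_PROMINENCE_FRACTION = 0.05
DEFAULT_EXCLUDED_PHASES = ("terminal_stance",)


class ConfigurationError(ValueError):
    """A pipeline parameter violates its preconditions."""


@dataclass(frozen=True)
class EventCandidate:
    """One extremum of one signal in one stride, referenced to a phase onset.

    ``offset`` = event time - onset time (seconds); negative offsets mean
    the event occurs before (anticipates) the referenced phase.
    """

    variable: str
    kind: str  # "max" or "min"
    stride_id: int
    time: float
    referenced_phase: str
    offset: float

    def __post_init__(self):
        if self.kind not in ("max", "min"):
            raise ValueError(f"kind must be 'max' or 'min', got {self.kind!r}")
        if self.referenced_phase not in PHASES:
            raise ValueError(f"unknown phase {self.referenced_phase!r}")
        if not np.isfinite(self.offset):
            raise ValueError("offset must be finite")


@dataclass
class EventSummary:
    """Stride-consistent event: timing distribution of one (variable, kind,
    phase) group across the analyzed strides."""

    variable: str
    kind: str
    phase: str
    n_strides_detected: int
    total_strides: int
    offsets: np.ndarray
    median_offset: float = field(init=False)
    iqr: float = field(init=False)

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.n_strides_detected > self.total_strides:
            raise ValueError("detected strides exceed total strides")
        self.median_offset = float(np.median(self.offsets))
        q1, q3 = np.percentile(self.offsets, [25, 75])
        self.iqr = float(q3 - q1)


def smooth(
    series: DerivedSeries,
    window: int = DEFAULT_SG_WINDOW,
    polyorder: int = SG_POLYORDER,
) -> DerivedSeries:
    """Savitzky-Golay smoothing of every channel.

    The default 11-sample window (0.22 s at 50 Hz) is shorter than any gait
    phase at walking cadence, preserving peak timing while removing
    high-frequency noise.  Invalid samples are bridged by interpolation
    before filtering and re-masked afterwards.

    Raises
    ------
    ConfigurationError
        If the window is even, not greater than the polynomial order, or
        longer than the series.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ConfigurationError(
            f"window must be odd and > polyorder={polyorder}, got {window}"
        )
    if series.n_samples < window:
        raise ConfigurationError(
            f"series length {series.n_samples} shorter than window {window}"
        )
    out = series.copy()
    t = series.timestamps
    for name, y in series.channels.items():
        ok = series.valid[name]
        if not ok.any():
            continue
        filled = _interpolate_invalid(t, y, ok)
        sm = savgol_filter(filled, window, polyorder)
        sm[~ok] = np.nan
        out.channels[name] = sm
    return out


def select_central_strides(tl: PhaseTimeline, n: int = DEFAULT_N_CENTRAL) -> PhaseTimeline:
    """Keep the n consecutive strides centered in the recording.

    When the surplus is odd the extra stride is discarded from the start of
    the recording.

    Raises
    ------
    InsufficientDataError
        If the timeline has fewer than n strides.
    """
    if tl.n_strides < n:
        raise InsufficientDataError(
            f"timeline has {tl.n_strides} strides; need >= {n}"
        )
    surplus = tl.n_strides - n
    start = (surplus + 1) // 2
    kept = tl.strides[start : start + n]
    return PhaseTimeline(strides=kept, recording_end=tl.stride_end(start + n - 1))


def _refine_peak_time(t: np.ndarray, y: np.ndarray, k: int) -> float:
    """Parabolic vertex through samples k-1, k, k+1 (falls back to t[k])."""
    if k <= 0 or k >= len(y) - 1:
        return float(t[k])
    ym, y0, yp = y[k - 1], y[k], y[k + 1]
    denom = ym - 2.0 * y0 + yp
    if denom == 0 or not np.isfinite(denom):
        return float(t[k])
    delta = 0.5 * (ym - yp) / denom
    if abs(delta) > 1.0:
        return float(t[k])
    return float(t[k] + delta * (t[min(k + 1, len(t) - 1)] - t[k]))


def _assign_phase(
    time: float,
    stride_id: int,
    tl: PhaseTimeline,
    excluded: tuple[str, ...],
) -> tuple[str, float]:
    """Reference an extremum to the phase onset with the smallest |offset|.

    Onsets of the extremum's own stride and the following stride are
    candidates; near-equidistant ties go to the following onset (the
    anticipating reading).
    """
    candidates: list[tuple[str, float]] = []
    for sid in (stride_id, stride_id + 1):
        if 0 <= sid < tl.n_strides:
            for phase in PHASES:
                if phase in excluded:
                    continue
                candidates.append((phase, tl.strides[sid][phase]))
    best = None
    for phase, onset in candidates:
        offset = time - onset
        if best is None:
            best = (phase, offset)
            continue
        if abs(offset) < abs(best[1]) - 1e-9:
            best = (phase, offset)
        elif abs(offset) <= abs(best[1]) + 1e-9 and offset < 0 <= best[1]:
            best = (phase, offset)  # tie: prefer the onset still ahead
    assert best is not None
    return best


def detect_stride_extrema(
    series: DerivedSeries,
    tl: PhaseTimeline,
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
    excluded_phases: tuple[str, ...] = DEFAULT_EXCLUDED_PHASES,
) -> list[EventCandidate]:
    """Detect per-stride local extrema of every channel.

    The prominence floor for a channel is ``prominence_fraction`` of its
    interquartile range over the analyzed strides, suppressing residual
    noise peaks; a flat channel therefore yields no candidates.  Extremum
    times are refined to sub-sample resolution by a parabolic fit.
    """
    t = series.timestamps
    t_start = tl.strides[0][PHASES[0]]
    t_end = tl.stride_end(tl.n_strides - 1)
    span = (t >= t_start) & (t <= t_end)

    out: list[EventCandidate] = []
    for name, y in series.channels.items():
        ok = series.valid[name]
        sel = span & ok
        if sel.sum() < 3:
            continue
        q1, q3 = np.percentile(y[sel], [25, 75])
        floor = prominence_fraction * (q3 - q1)
        if floor <= 0:
            continue  # flat channel
        filled = _interpolate_invalid(t, y, ok) if not ok.all() else y
        for stride_id in range(tl.n_strides):
            lo = tl.strides[stride_id][PHASES[0]]
            hi = tl.stride_end(stride_id)
            idx = np.flatnonzero((t >= lo) & (t < hi))
            if len(idx) < 3:
                continue
            seg = filled[idx]
            for kind, sig in (("max", seg), ("min", -seg)):
                peaks, _ = find_peaks(sig, prominence=floor)
                for p in peaks:
                    k = idx[p]
                    if not ok[k]:
                        continue
                    time = _refine_peak_time(t[idx], seg, p)
                    phase, offset = _assign_phase(time, stride_id, tl, excluded_phases)
                    out.append(
                        EventCandidate(
                            variable=name,
                            kind=kind,
                            stride_id=stride_id,
                            time=time,
                            referenced_phase=phase,
                            offset=offset,
                        )
                    )
    return out


def consolidate_events(
    cands: list[EventCandidate],
    min_strides: int = DEFAULT_MIN_STRIDES,
    total_strides: int = DEFAULT_N_CENTRAL,
) -> list[EventSummary]:
    """Keep events that recur in at least ``min_strides`` strides.

    Candidates are grouped by (variable, kind, referenced phase); a stride
    counts once per group (if a stride contributes several candidates the
    one closest to the onset represents it).  Groups below the consistency
    threshold are dropped.
    """
    groups: dict[tuple[str, str, str], dict[int, float]] = {}
    for c in cands:
        key = (c.variable, c.kind, c.referenced_phase)
        per_stride = groups.setdefault(key, {})
        prev = per_stride.get(c.stride_id)
        if prev is None or abs(c.offset) < abs(prev):
            per_stride[c.stride_id] = c.offset
    summaries = []
    for (variable, kind, phase), per_stride in sorted(groups.items()):
        n = len(per_stride)
        if n < min_strides:
            continue
        offsets = np.array([per_stride[s] for s in sorted(per_stride)])
        summaries.append(
            EventSummary(
                variable=variable,
                kind=kind,
                phase=phase,
                n_strides_detected=n,
                total_strides=total_strides,
                offsets=offsets,
            )
        )
    return summaries


@dataclass
class NormalizedStrides:
    """Per-stride channel curves on a common [0, 1] stride-time grid.

    0 is the stride's initial contact and 1 the next initial contact.
    ``curves[name]`` has shape (n_strides, n_points); ``mean_curves`` is the
    across-stride mean; ``phase_fractions`` the mean onset position of each
    phase as a fraction of the stride.
    """

    grid: np.ndarray
    curves: dict[str, np.ndarray]
    mean_curves: dict[str, np.ndarray]
    phase_fractions: dict[str, float]


def normalize_stride_time(
    series: DerivedSeries,
    tl: PhaseTimeline,
    n_points: int = 101,
) -> NormalizedStrides:
    """Resample each stride of each channel onto a normalized time grid.

    Useful for visual inspection of how a variable evolves across the gait
    cycle: strides of unequal duration become directly comparable, and the
    mean curve with mean phase-onset lines mirrors the usual gait-cycle
    plot.
    """
    if tl.n_strides < 1:
        raise InsufficientDataError("need at least one stride")
    grid = np.linspace(0.0, 1.0, n_points)
    t = series.timestamps
    curves: dict[str, np.ndarray] = {}
    for name, y in series.channels.items():
        filled = _interpolate_invalid(t, y, series.valid[name])
        rows = np.empty((tl.n_strides, n_points))
        for i in range(tl.n_strides):
            lo = tl.strides[i][PHASES[0]]
            hi = tl.stride_end(i)
            rows[i] = np.interp(lo + grid * (hi - lo), t, filled)
        curves[name] = rows
    mean_curves = {k: v.mean(axis=0) for k, v in curves.items()}
    phase_fractions = {}
    for phase in PHASES:
        fr = [
            (tl.strides[i][phase] - tl.strides[i][PHASES[0]])
            / (tl.stride_end(i) - tl.strides[i][PHASES[0]])
            for i in range(tl.n_strides)
        ]
        phase_fractions[phase] = float(np.mean(fr))
    return NormalizedStrides(grid, curves, mean_curves, phase_fractions)
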
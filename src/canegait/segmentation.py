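"""Rule-based gait-phase segmentation of the reference kinematics stream.

The reference stream (an inertial motion-capture system) provides, at a rate
higher than the cane's 50 Hz, the speed and sagittal orientation of each
foot, the tibia angle of the tracked (impaired-side) leg, the horizontal
distance between the feet, and the cane inclination.  A stride runs between
two successive initial contacts of the tracked foot, and is split into seven
phases (initial contact is merged with loading response, since on its own it
covers only ~8% of the cycle):

========================================  =======================================
phase onset                               detection rule
========================================  =======================================
initial_contact_loading_response          tracked-foot speed falls below the
                                          stance threshold after a swing interval
mid_stance                                opposite-foot speed rises above the
                                          swing threshold (opposite toe-off)
terminal_stance                           tracked foot angle rises above 0
                                          (heel rise) while speed stays in stance
pre_swing                                 opposite-foot speed falls below the
                                          stance threshold (opposite contact)
initial_swing                             tracked-foot speed exceeds the swing
                                          threshold with toe-down foot angle
mid_swing                                 feet-adjacent: local minimum of the
                                          inter-feet distance below 0.4 m
terminal_swing                            tibia angle crosses vertical (90 deg
                                          from horizontal), interpolated
========================================  =======================================

Onsets are searched sequentially inside each stride, each after the previous
one, with a small sample hysteresis on every threshold crossing to suppress
chatter.  Strides missing any onset are dropped as incomplete.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelextrema

from .variables import InsufficientDataError

PHASES = (
    "initial_contact_loading_response",
    "mid_stance",
    "terminal_stance",
    "pre_swing",
    "initial_swing",
    "mid_swing",
    "terminal_swing",
)


@dataclass
class KinematicsSeries:
    """Reference kinematics, one row per sample.

    All arrays share ``timestamps`` (seconds, strictly increasing).  Speeds
    are m/s, angles degrees (foot angle: sagittal, 0 = foot flat, negative =
    toe down; tibia angle: from the horizontal axis, 90 = vertical), the
    inter-feet distance metres, and the cane angle degrees from vertical.
    """

    timestamps: np.ndarray
    tracked_foot_speed: np.ndarray
    opposite_foot_speed: np.ndarray
    tracked_foot_angle: np.ndarray
    tibia_angle: np.ndarray
    feet_distance: np.ndarray
    cane_angle: np.ndarray

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        n = len(self.timestamps)
        for name in (
            "tracked_foot_speed",
            "opposite_foot_speed",
            "tracked_foot_angle",
            "tibia_angle",
            "feet_distance",
            "cane_angle",
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n:
                raise ValueError(f"{name} length mismatch")
            setattr(self, name, arr)
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.feet_distance < 0):
            raise ValueError("feet_distance must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds of the segmentation rules.

    Defaults are the reference values used throughout: a foot moving slower
    than 0.4 m/s is in stance, faster than 0.8 m/s in swing; heel-off
    requires a toe-down angle below -9 deg at toe-off; the feet-adjacent
    minimum must fall below 0.4 m; vertical tibia is 90 deg from horizontal.
    ``hysteresis_samples`` is the number of samples a crossing must persist
    on both sides to count.
    """

    stance_speed_threshold: float = 0.4
    swing_speed_threshold: float = 0.8
    foot_angle_threshold: float = -9.0
    feet_distance_threshold: float = 0.4
    tibia_vertical_angle: float = 90.0
    hysteresis_samples: int = 2

    def __post_init__(self):
        vals = (
            self.stance_speed_threshold,
            self.swing_speed_threshold,
            self.foot_angle_threshold,
            self.feet_distance_threshold,
            self.tibia_vertical_angle,
        )
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("thresholds must be finite")
        if not self.stance_speed_threshold < self.swing_speed_threshold:
            raise ValueError(
                "stance_speed_threshold must be below swing_speed_threshold"
            )
        if self.hysteresis_samples < 1:
            raise ValueError("hysteresis_samples must be >= 1")


@dataclass
class PhaseTimeline:
    """Ordered phase-onset times for a sequence of complete strides.

    ``strides`` maps each phase label of :data:`PHASES` to its onset time in
    seconds; within a stride onsets strictly increase in canonical order and
    consecutive strides do not overlap.  ``recording_end`` closes the last
    stride for duration computations.
    """

    strides: list[dict[str, float]]
    recording_end: float | None = None

    def __post_init__(self):
        for k, stride in enumerate(self.strides):
            missing = [p for p in PHASES if p not in stride]
            if missing:
                raise ValueError(f"stride {k} missing phases: {missing}")
            onsets = [stride[p] for p in PHASES]
            if not np.all(np.diff(onsets) > 0):
                raise ValueError(f"stride {k} onsets not strictly increasing")
            if k > 0 and stride[PHASES[0]] <= self.strides[k - 1][PHASES[-1]]:
                raise ValueError(f"stride {k} overlaps stride {k - 1}")

    @property
    def n_strides(self) -> int:
        return len(self.strides)

    def initial_contacts(self) -> np.ndarray:
        return np.array([s[PHASES[0]] for s in self.strides])

    def stride_end(self, i: int) -> float:
        """End time of stride i: the next initial contact, or recording end."""
        if i + 1 < self.n_strides:
            return self.strides[i + 1][PHASES[0]]
        if self.recording_end is not None:
            return self.recording_end
        raise ValueError("last stride has no recording_end to close it")


def _sustained_crossings(
    t: np.ndarray,
    y: np.ndarray,
    threshold: float,
    direction: str,
    hysteresis: int,
) -> list[tuple[int, float]]:
    """Indices and interpolated times where y crosses a threshold.

    A crossing at sample k counts only if the condition (above for 'up',
    below for 'down') holds for ``hysteresis`` samples from k and failed for
    ``hysteresis`` samples before k.
    """
    cond = y > threshold if direction == "up" else y < threshold
    n = len(y)
    flips = np.flatnonzero(cond[1:] & ~cond[:-1]) + 1
    out = []
    for k in flips:
        if k < hysteresis or k + hysteresis > n:
            continue
        if not cond[k : k + hysteresis].all():
            continue
        if cond[k - hysteresis : k].any():
            continue
        y0, y1 = y[k - 1], y[k]
        if y1 == y0:
            tc = t[k]
        else:
            tc = t[k - 1] + (threshold - y0) / (y1 - y0) * (t[k] - t[k - 1])
        out.append((int(k), float(tc)))
    return out


def _first_crossing_after(
    crossings: list[tuple[int, float]], after: float, before: float
) -> tuple[int, float] | None:
    for k, tc in crossings:
        if after < tc < before:
            return k, tc
    return None


def detect_initial_contacts(
    kin: KinematicsSeries, cfg: SegmentationConfig
) -> list[tuple[int, float]]:
    """Initial contacts of the tracked foot.

    A contact is a sustained fall of the tracked-foot speed below the stance
    threshold that is preceded by a swing interval (speed above the swing
    threshold since the previous contact); spurious in-stance dips are thus
    ignored.
    """
    t = kin.timestamps
    v = kin.tracked_foot_speed
    downs = _sustained_crossings(
        t, v, cfg.stance_speed_threshold, "down", cfg.hysteresis_samples
    )
    ics = []
    prev_idx = 0
    for k, tc in downs:
        if np.max(v[prev_idx:k]) > cfg.swing_speed_threshold:
            ics.append((k, tc))
            prev_idx = k
    return ics


def segment_gait(kin: KinematicsSeries, cfg: SegmentationConfig | None = None) -> PhaseTimeline:
    """Segment reference kinematics into per-stride phase onsets.

    Returns one timeline entry per complete stride of the tracked foot;
    leading/trailing incomplete strides (and strides missing any phase, e.g.
    a feet-adjacent minimum that never drops below the distance threshold)
    are dropped.

    Raises
    ------
    InsufficientDataError
        If fewer than 3 complete strides are found.
    """
    if cfg is None:
        cfg = SegmentationConfig()
    t = kin.timestamps
    h = cfg.hysteresis_samples

    ics = detect_initial_contacts(kin, cfg)
    if len(ics) < 2:
        raise InsufficientDataError(
            f"found {len(ics)} initial contacts; need >=4 for 3 complete strides"
        )

    opp_ups = _sustained_crossings(
        t, kin.opposite_foot_speed, cfg.swing_speed_threshold, "up", h
    )
    opp_downs = _sustained_crossings(
        t, kin.opposite_foot_speed, cfg.stance_speed_threshold, "down", h
    )
    angle_ups = _sustained_crossings(t, kin.tracked_foot_angle, 0.0, "up", h)
    speed_ups = _sustained_crossings(
        t, kin.tracked_foot_speed, cfg.swing_speed_threshold, "up", h
    )
    tibia_cross = sorted(
        _sustained_crossings(t, kin.tibia_angle, cfg.tibia_vertical_angle, "up", h)
        + _sustained_crossings(t, kin.tibia_angle, cfg.tibia_vertical_angle, "down", h),
        key=lambda c: c[1],
    )
    dist_min_idx = argrelextrema(kin.feet_distance, np.less_equal, order=h)[0]

    strides: list[dict[str, float]] = []
    for (k0, t_ic), (k1, t_next) in zip(ics[:-1], ics[1:]):
        onsets: dict[str, float] = {PHASES[0]: t_ic}
        cursor = t_ic

        c = _first_crossing_after(opp_ups, cursor, t_next)
        if c is None:
            continue
        onsets["mid_stance"] = cursor = c[1]

        # heel rise: foot angle up-crossing of 0 while still in stance speed
        ts_onset = None
        for k, tc in angle_ups:
            if cursor < tc < t_next and kin.tracked_foot_speed[k] < cfg.stance_speed_threshold:
                ts_onset = tc
                break
        if ts_onset is None:
            continue
        onsets["terminal_stance"] = cursor = ts_onset

        c = _first_crossing_after(opp_downs, cursor, t_next)
        if c is None:
            continue
        onsets["pre_swing"] = cursor = c[1]

        # toe-off: swing speed reached with toe-down foot angle
        isw_onset = None
        for k, tc in speed_ups:
            if cursor < tc < t_next and kin.tracked_foot_angle[k] < cfg.foot_angle_threshold:
                isw_onset = tc
                break
        if isw_onset is None:
            continue
        onsets["initial_swing"] = cursor = isw_onset

        # feet adjacent: qualifying minimum of the inter-feet distance
        msw_onset = None
        for k in dist_min_idx:
            if cursor < t[k] < t_next and kin.feet_distance[k] < cfg.feet_distance_threshold:
                msw_onset = float(t[k])
                break
        if msw_onset is None:
            continue
        onsets["mid_swing"] = cursor = msw_onset

        c = _first_crossing_after(tibia_cross, cursor, t_next)
        if c is None:
            continue
        onsets["terminal_swing"] = c[1]

        strides.append(onsets)

    if len(strides) < 3:
        raise InsufficientDataError(
            f"only {len(strides)} complete strides segmented; need >=3"
        )
    return PhaseTimeline(strides=strides, recording_end=float(t[-1]))


def stride_durations(tl: PhaseTimeline) -> np.ndarray:
    """Stride durations in seconds.

    Duration i is the time between consecutive initial contacts; the last
    stride is closed by the recording end.

    Raises
    ------
    InsufficientDataError
        If the timeline holds no strides.
    """
    if tl.n_strides == 0:
        raise InsufficientDataError("empty timeline")
    ic = tl.initial_contacts()
    last_end = tl.stride_end(tl.n_strides - 1)
    return np.diff(np.append(ic, last_end))
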
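"""Ground-truthed synthetic cane-gait recordings.

The simulator emulates the measurement setup end to end: a subject walks at
steady cadence holding the cane contralaterally, so the cane moves in
synchrony with the tracked (impaired-side) leg.  It emits

* a reference kinematics stream (foot speeds, foot angle, tibia angle,
  inter-feet distance, cane inclination) at ``ref_rate``, constructed from
  cyclic piecewise-linear templates so that every segmentation rule fires
  exactly at the configured phase fraction of each stride;
* a cane stream (16 FSR channels plus the cane inclination seen by the cane
  IMU) at ``fsr_rate``, on a clock offset by ``injected_lag`` seconds;
* the ground truth: the phase timeline, the lag, and the per-stride times of
  every planted extremum.

The grip pattern is a shared stride-periodic load curve (loading during cane
stance, near-release during cane swing) distributed over the 16 sensors with
fixed per-channel weights.  With fixed weights the grip centre-of-pressure
variables are constant by construction, so every detected extremum of a CoM
variable is a planted one: events are planted as Gaussian force bumps (or
error-function steps, for events in the derivative variables) on
variable-specific sensor subsets, which moves the chosen variable up or down
exactly around the planted cycle fraction.

The cane inclination is stride-periodic with a slow incommensurate amplitude
envelope emulating stride-to-stride variability; the envelope is what makes
the inter-stream lag identifiable beyond one stride period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .events import ConfigurationError
from .layout import HandleLayout, load_default_layout
from .segmentation import PHASES, KinematicsSeries, PhaseTimeline
from .variables import BASE_VARIABLES, FSRSeries

DEFAULT_PHASE_FRACTIONS = {
    "initial_contact_loading_response": 0.0,
    "mid_stance": 0.10,
    "terminal_stance": 0.30,
    "pre_swing": 0.50,
    "initial_swing": 0.60,
    "mid_swing": 0.73,
    "terminal_swing": 0.87,
}

#: slow amplitude-envelope period of the cane swing, seconds; deliberately
#: incommensurate with the stride period
ENVELOPE_PERIOD = 13.7


@dataclass(frozen=True)
class PlantedEvent:
    """An extremum to plant in one derived variable.

    ``channel`` is one of the 6 base variables or a ``d``-prefixed
    derivative; ``cycle_fraction`` the stride fraction of the extremum;
    ``amplitude`` the force-bump height in sensor units; ``jitter_sd`` a
    per-stride Gaussian jitter of the extremum time in seconds.
    """

    channel: str
    kind: str
    cycle_fraction: float
    amplitude: float = 1.0
    jitter_sd: float = 0.0

    def __post_init__(self):
        base = self.channel[1:] if self.channel.startswith("d") else self.channel
        if base not in BASE_VARIABLES:
            raise ConfigurationError(f"unknown channel {self.channel!r}")
        if self.kind not in ("max", "min"):
            raise ConfigurationError("kind must be 'max' or 'min'")
        if not 0.0 < self.cycle_fraction < 1.0:
            raise ConfigurationError("cycle_fraction must be in (0, 1)")


@dataclass(frozen=True)
class GaitSimConfig:
    """Study conditions for one simulated recording.

    Defaults emulate the reference protocol: steady treadmill walking, a
    1.1 s stride, the cane scanned at 50 Hz, the motion-capture reference at
    100 Hz, and enough strides (40) to select 30 central ones.
    """

    n_strides: int = 40
    stride_period: float = 1.1
    phase_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_FRACTIONS)
    )
    fsr_rate: float = 50.0
    ref_rate: float = 100.0
    injected_lag: float = 0.0
    planted_events: tuple[PlantedEvent, ...] = ()
    noise_sd_fsr: float = 0.02
    noise_sd_kin: float = 0.01
    noise_sd_cane: float = 0.1
    feet_min_distance: float = 0.12
    seed: int = 0

    def __post_init__(self):
        if self.n_strides < 3:
            raise ConfigurationError("n_strides must be >= 3")
        if self.stride_period <= 0 or self.fsr_rate <= 0 or self.ref_rate <= 0:
            raise ConfigurationError("periods and rates must be positive")
        fr = self.phase_fractions
        missing = [p for p in PHASES if p not in fr]
        if missing:
            raise ConfigurationError(f"phase_fractions missing {missing}")
        if fr[PHASES[0]] != 0.0:
            raise ConfigurationError("initial contact fraction must be 0")
        vals = [fr[p] for p in PHASES]
        if not all(0.0 <= v < 1.0 for v in vals):
            raise ConfigurationError("phase fractions must lie in [0, 1)")
        gaps = np.diff(vals)
        if np.any(gaps < 0.05):
            raise ConfigurationError(
                "phase fractions must increase by >= 0.05 in canonical order"
            )
        if vals[-1] > 0.95:
            raise ConfigurationError("terminal_swing fraction must be <= 0.95")


@dataclass
class CaneRecording:
    """The cane acquisition stream: FSR forces plus cane inclination."""

    fsr: FSRSeries
    cane_angle: np.ndarray

    def __post_init__(self):
        self.cane_angle = np.asarray(self.cane_angle, dtype=float)
        if len(self.cane_angle) != self.fsr.n_samples:
            raise ValueError("cane_angle length mismatch")


@dataclass
class GroundTruth:
    """What the simulator actually generated.

    ``timeline``: the true phase timeline; ``lag``: the injected clock
    offset (add it to cane timestamps to align); ``event_times``: per
    planted event, the per-stride extremum times on the reference clock.
    """

    timeline: PhaseTimeline
    lag: float
    event_times: dict[tuple[str, str], np.ndarray]


def _cyclic_template(points: list[tuple[float, float]]):
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])

    def f(phi: np.ndarray) -> np.ndarray:
        return np.interp(np.mod(phi, 1.0), xs, ys)

    return f


def _build_templates(fr: dict[str, float], d_min: float):
    ms = fr["mid_stance"]
    ts = fr["terminal_stance"]
    ps = fr["pre_swing"]
    isw = fr["initial_swing"]
    msw = fr["mid_swing"]
    tsw = fr["terminal_swing"]

    tracked_speed = _cyclic_template(
        [
            (0.0, 0.4),
            (0.04, 0.08),
            (isw - 0.04, 0.08),
            (isw, 0.8),
            (min(isw + 0.05, 0.90), 3.0),
            (0.93, 3.0),
            (1.0, 0.4),
        ]
    )
    opposite_speed = _cyclic_template(
        [
            (0.0, 0.08),
            (max(ms - 0.05, 0.01), 0.08),
            (ms, 0.8),
            (min(ms + 0.05, ps - 0.12), 3.0),
            (ps - 0.10, 3.0),
            (ps, 0.4),
            (min(ps + 0.04, 0.99), 0.08),
            (1.0, 0.08),
        ]
    )
    foot_angle = _cyclic_template(
        [
            (0.0, -3.0),
            (ts - 0.05, -3.0),
            (ts, 0.0),
            (ts + 0.04, 8.0),
            (ps + 0.02, 8.0),
            (isw - 0.02, -15.0),
            (0.93, -15.0),
            (1.0, -3.0),
        ]
    )
    feet_distance = _cyclic_template([(0.0, 0.7), (msw, d_min), (1.0, 0.7)])
    tibia_angle = _cyclic_template(
        [
            (0.0, 95.0),
            (isw, 70.0),
            (msw, 75.0),
            (tsw - 0.05, 85.0),
            (tsw, 90.0),
            (1.0, 95.0),
        ]
    )
    return tracked_speed, opposite_speed, foot_angle, feet_distance, tibia_angle


def _grip_load(phi: np.ndarray) -> np.ndarray:
    """Stride-periodic shared load: loading peak mid-stance, residual grip
    during swing (the hand never fully releases the handle)."""
    out = np.full_like(phi, 0.12)
    p = np.mod(phi, 1.0)
    for k in (-1, 0, 1):
        out = out + 0.9 * np.exp(-0.5 * ((p - 0.30 - k) / 0.16) ** 2)
    return out


#: fixed per-channel share of the grip load (ids 1..16); mild variation so
#: no sensor dominates, constant over time so CoM variables stay flat
_CHANNEL_WEIGHTS = 0.5 + 0.04 * np.arange(16) % 0.6 + 0.3 * np.cos(
    np.linspace(0.0, 2.5, 16)
)


def _event_sensor_sets(layout: HandleLayout) -> dict[tuple[str, str], np.ndarray]:
    """Sensor subsets whose loading raises (max) or lowers (min) a variable."""
    x, z = layout.x, layout.z
    top, bottom = layout.top_mask, layout.bottom_mask
    x_med = np.median(x)
    sets = {
        ("CoMZ", "max"): top,
        ("CoMZ", "min"): bottom,
        ("CoMX", "max"): x >= x_med,
        ("CoMX", "min"): x < x_med,
        ("CoMXUp", "max"): top & (x >= np.median(x[top])),
        ("CoMXUp", "min"): top & (x < np.median(x[top])),
        ("CoMXDown", "max"): bottom & (x >= np.median(x[bottom])),
        ("CoMXDown", "min"): bottom & (x < np.median(x[bottom])),
        ("MPUp", "max"): top,
        ("MPUp", "min"): top,  # applied as a multiplicative dip
        ("MPDown", "max"): bottom,
        ("MPDown", "min"): bottom,
    }
    return {k: v.astype(bool) for k, v in sets.items()}


def cane_inclination(t: np.ndarray, stride_period: float, t0: float) -> np.ndarray:
    """True cane angle from vertical (degrees) at reference-clock times t.

    Stride-periodic swing with a slow amplitude envelope; defined for all t
    so either stream clock can sample it.
    """
    t = np.asarray(t, dtype=float)
    amp = 12.0 + 3.0 * np.sin(2.0 * math.pi * t / ENVELOPE_PERIOD)
    return 2.0 + amp * np.cos(2.0 * math.pi * (t - t0) / stride_period)


def simulate(
    cfg: GaitSimConfig, layout: HandleLayout | None = None
) -> tuple[CaneRecording, KinematicsSeries, GroundTruth]:
    """Generate one synthetic recording with its ground truth.

    The reference stream spans a half-stride lead-in, ``n_strides`` complete
    strides, and enough trailing signal to close the last stride; the cane
    stream covers the same span on a clock shifted by ``injected_lag``
    (adding the lag to cane timestamps recovers the reference clock).
    Identical configs give bitwise-identical outputs.
    """
    if layout is None:
        layout = load_default_layout()
    rng = np.random.default_rng(cfg.seed)
    T = cfg.stride_period
    t0 = 0.5 * T  # lead-in: half a stride of swing before the first contact
    duration = t0 + (cfg.n_strides + 0.6) * T

    # --- reference kinematics stream -------------------------------------
    n_ref = int(np.floor(duration * cfg.ref_rate)) + 1
    t_ref = np.arange(n_ref) / cfg.ref_rate
    phi = (t_ref - t0) / T
    tr_speed, op_speed, f_angle, f_dist, tib = _build_templates(
        cfg.phase_fractions, cfg.feet_min_distance
    )
    s = cfg.noise_sd_kin
    kin = KinematicsSeries(
        timestamps=t_ref,
        tracked_foot_speed=np.clip(
            tr_speed(phi) + rng.normal(0, s, n_ref), 0, None
        ),
        opposite_foot_speed=np.clip(
            op_speed(phi) + rng.normal(0, s, n_ref), 0, None
        ),
        tracked_foot_angle=f_angle(phi) + rng.normal(0, 10 * s, n_ref),
        tibia_angle=tib(phi) + rng.normal(0, 10 * s, n_ref),
        feet_distance=np.clip(f_dist(phi) + rng.normal(0, 0.1 * s, n_ref), 0, None),
        cane_angle=cane_inclination(t_ref, T, t0)
        + rng.normal(0, cfg.noise_sd_cane, n_ref),
    )

    # --- ground-truth timeline --------------------------------------------
    strides = []
    for k in range(cfg.n_strides):
        strides.append(
            {p: t0 + (k + cfg.phase_fractions[p]) * T for p in PHASES}
        )
    timeline = PhaseTimeline(strides=strides, recording_end=t0 + cfg.n_strides * T)

    # --- cane stream -------------------------------------------------------
    n_fsr = int(np.floor(duration * cfg.fsr_rate)) + 1
    t_cane = np.arange(n_fsr) / cfg.fsr_rate
    t_true = t_cane + cfg.injected_lag  # physical time each sample observes
    load = _grip_load((t_true - t0) / T)
    forces = np.outer(load, _CHANNEL_WEIGHTS)

    sensor_sets = _event_sensor_sets(layout)
    sigma_b = 0.04 * T
    phi_cdf = lambda u: 0.5 * (1.0 + erf(u / math.sqrt(2.0)))  # noqa: E731
    event_times: dict[tuple[str, str], np.ndarray] = {}
    for ev in cfg.planted_events:
        centers = (
            t0
            + (np.arange(cfg.n_strides) + ev.cycle_fraction) * T
            + rng.normal(0.0, ev.jitter_sd, cfg.n_strides)
        )
        event_times[(ev.channel, ev.kind)] = centers
        base = ev.channel[1:] if ev.channel.startswith("d") else ev.channel
        mask = sensor_sets[(base, ev.kind)]
        bump = np.zeros(n_fsr)
        for c in centers:
            u = (t_true - c) / sigma_b
            if ev.channel.startswith("d"):
                # non-negative pulse whose steep edge sits at c: the parent
                # variable then has its sharpest slope (a d-extremum) at c
                if ev.kind == "max":
                    pulse = phi_cdf(u) * (1.0 - phi_cdf(u - 10.0))
                else:
                    pulse = phi_cdf(u + 10.0) * (1.0 - phi_cdf(u))
                bump += ev.amplitude * pulse
            else:
                bump += ev.amplitude * np.exp(-0.5 * u * u)
        if base.startswith("MP") and ev.kind == "min" and not ev.channel.startswith("d"):
            # mean pressure can only be lowered by unloading: multiplicative dip
            dip = np.clip(1.0 - 0.6 * bump / max(ev.amplitude, 1e-12), 0.0, 1.0)
            forces[:, mask] *= dip[:, None]
        else:
            forces[:, mask] += bump[:, None]

    forces = np.clip(forces + rng.normal(0, cfg.noise_sd_fsr, forces.shape), 0, None)
    fsr = FSRSeries(timestamps=t_cane, forces=forces)
    cane_angle = cane_inclination(t_true, T, t0) + rng.normal(
        0, cfg.noise_sd_cane, n_fsr
    )

    truth = GroundTruth(timeline=timeline, lag=cfg.injected_lag, event_times=event_times)
    return CaneRecording(fsr=fsr, cane_angle=cane_angle), kin, truth


def corrupt(
    values: np.ndarray,
    dropout_fraction: float = 0.0,
    spike_rate: float = 0.0,
    spike_amplitude: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Robustness harness: zero out samples and inject additive spikes.

    ``dropout_fraction`` of the samples (rows, for multi-channel arrays) are
    zeroed i.i.d.; ``spike_rate`` of the samples get an additive spike of
    ``spike_amplitude``.  Ground truth is untouched; the caller decides which
    stream to corrupt.
    """
    if not 0.0 <= dropout_fraction < 1.0 or not 0.0 <= spike_rate < 1.0:
        raise ConfigurationError("fractions must lie in [0, 1)")
    out = np.array(values, dtype=float, copy=True)
    rng = np.random.default_rng(seed)
    n = out.shape[0]
    if dropout_fraction > 0:
        out[rng.random(n) < dropout_fraction] = 0.0
    if spike_rate > 0:
        hit = rng.random(n) < spike_rate
        if out.ndim == 1:
            out[hit] += spike_amplitude
        else:
            cols = rng.integers(0, out.shape[1], size=int(hit.sum()))
            out[np.flatnonzero(hit), cols] += spike_amplitude
    return out
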
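"""Grip-pressure variables derived from the 16-channel FSR series.

Six per-sample variables are computed from the raw sensor outputs f(i) and
the sensor coordinates (x(i), z(i)):

* ``CoMXUp``   — force-weighted mean x over the 10 top-side sensors,
* ``CoMXDown`` — force-weighted mean x over the 6 bottom-side sensors,
* ``CoMX``     — force-weighted mean x over all 16 sensors,
* ``CoMZ``     — force-weighted mean z over all 16 sensors,
* ``MPUp``     — mean output of the top-side sensors (sum / 10),
* ``MPDown``   — mean output of the bottom-side sensors (sum / 6).

The CoM variables are grip centre-of-pressure analogues in millimetres; the
mean-pressure variables stay in raw conditioned sensor units (FSRs are
reliable for timing, not for absolute force).  Their time derivatives carry a
``d`` prefix (``dCoMZ`` is the time derivative of ``CoMZ``).

A CoM value is undefined whenever the aggregated force sum is zero (e.g. a
fully unloaded handle during cane swing); such samples are flagged in a
validity mask rather than filled with a fabricated number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layout import HandleLayout, N_SENSORS

COM_VARIABLES = ("CoMXUp", "CoMXDown", "CoMX", "CoMZ")
MP_VARIABLES = ("MPUp", "MPDown")
BASE_VARIABLES = COM_VARIABLES + MP_VARIABLES
DERIVATIVE_VARIABLES = tuple("d" + v for v in BASE_VARIABLES)
ALL_VARIABLES = BASE_VARIABLES + DERIVATIVE_VARIABLES


class ChannelCountError(ValueError):
    """FSR series channel count does not match the handle layout."""


class InsufficientDataError(ValueError):
    """Operation needs more samples than the series provides."""


@dataclass
class FSRSeries:
    """Multi-channel FSR recording.

    Parameters
    ----------
    timestamps : array, seconds
        Strictly increasing sample times, nominally uniform at 50 Hz.
    forces : array, shape (n_samples, 16)
        Non-negative conditioned sensor outputs, column i holding sensor
        id ``layout.sensor_id[i]`` (ascending id order).
    """

    timestamps: np.ndarray
    forces: np.ndarray

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        if self.forces.ndim != 2:
            raise ValueError("forces must be 2-D (samples x channels)")
        if len(self.timestamps) != self.forces.shape[0]:
            raise ValueError("one force vector required per timestamp")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.forces < 0):
            raise ValueError("sensor outputs must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def n_channels(self) -> int:
        return self.forces.shape[1]


@dataclass
class DerivedSeries:
    """Derived grip variables (and optionally their derivatives) over time.

    ``channels`` maps a variable name to a float array aligned with
    ``timestamps``; ``valid`` maps the same name to a boolean mask that is
    False where the variable is undefined (zero aggregated force for CoM
    variables).  MP variables are always valid.
    """

    timestamps: np.ndarray
    channels: dict[str, np.ndarray]
    valid: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        n = len(self.timestamps)
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if len(arr) != n:
                raise ValueError(f"channel {name} length mismatch")
            self.channels[name] = arr
        for name in self.channels:
            mask = self.valid.get(name)
            if mask is None:
                mask = np.isfinite(self.channels[name])
            self.valid[name] = np.asarray(mask, dtype=bool)

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    def channel_names(self) -> list[str]:
        return list(self.channels)

    def copy(self) -> "DerivedSeries":
        return DerivedSeries(
            timestamps=self.timestamps.copy(),
            channels={k: v.copy() for k, v in self.channels.items()},
            valid={k: v.copy() for k, v in self.valid.items()},
        )


def compute_derived(series: FSRSeries, layout: HandleLayout) -> DerivedSeries:
    """Compute the six grip variables per sample from an FSR series.

    CoM variables are force-weighted means of sensor coordinates over the
    relevant sensor subset; MP variables are subset force sums divided by the
    subset size.  Samples whose weighting denominator is zero are masked
    invalid (NaN value, False in the validity mask) instead of fabricated.

    Raises
    ------
    ChannelCountError
        If the series channel count differs from the layout sensor count.
    """
    if series.n_channels != layout.n_sensors:
        raise ChannelCountError(
            f"series has {series.n_channels} channels, layout has "
            f"{layout.n_sensors} sensors"
        )
    f = series.forces
    top = layout.top_mask
    bottom = layout.bottom_mask
    n_up = int(top.sum())
    n_down = int(bottom.sum())

    def weighted_mean(coord: np.ndarray, mask: np.ndarray):
        w = f[:, mask]
        denom = w.sum(axis=1)
        ok = denom > 0
        out = np.full(series.n_samples, np.nan)
        num = w @ coord[mask]
        out[ok] = num[ok] / denom[ok]
        return out, ok

    channels: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}
    all_mask = np.ones(layout.n_sensors, dtype=bool)
    for name, coord, mask in (
        ("CoMXUp", layout.x, top),
        ("CoMXDown", layout.x, bottom),
        ("CoMX", layout.x, all_mask),
        ("CoMZ", layout.z, all_mask),
    ):
        channels[name], valid[name] = weighted_mean(coord, mask)
    channels["MPUp"] = f[:, top].sum(axis=1) / n_up
    channels["MPDown"] = f[:, bottom].sum(axis=1) / n_down
    valid["MPUp"] = np.ones(series.n_samples, dtype=bool)
    valid["MPDown"] = np.ones(series.n_samples, dtype=bool)
    return DerivedSeries(series.timestamps.copy(), channels, valid)


def _interpolate_invalid(t: np.ndarray, y: np.ndarray, ok: np.ndarray) -> np.ndarray:
    """Fill invalid samples by linear interpolation over valid neighbours."""
    if ok.all():
        return y
    if not ok.any():
        return np.zeros_like(y)
    out = y.copy()
    out[~ok] = np.interp(t[~ok], t[ok], y[ok])
    return out


def differentiate(series: DerivedSeries) -> DerivedSeries:
    """Append time-derivative channels (``d`` prefix) to a derived series.

    Central finite differences on the interior, one-sided at the ends
    (``numpy.gradient`` on the actual timestamps).  Invalid samples are
    bridged by linear interpolation before differencing and re-masked
    afterwards, so the mask of ``dX`` equals the mask of ``X``.

    Raises
    ------
    InsufficientDataError
        If the series has fewer than 3 samples.
    """
    if series.n_samples < 3:
        raise InsufficientDataError(
            f"need >=3 samples to differentiate, got {series.n_samples}"
        )
    out = series.copy()
    t = series.timestamps
    for name in list(series.channels):
        if name.startswith("d"):
            continue
        ok = series.valid[name]
        if ok.sum() < 3:
            raise InsufficientDataError(
                f"channel {name} has fewer than 3 valid samples"
            )
        y = _interpolate_invalid(t, series.channels[name], ok)
        dy = np.gradient(y, t)
        dy[~ok] = np.nan
        out.channels["d" + name] = dy
        out.valid["d" + name] = ok.copy()
    return out


def compute_derived_naive(series: FSRSeries, layout: HandleLayout) -> DerivedSeries:
    """Reference per-sample loop implementation of :func:`compute_derived`.

    Kept deliberately naive (explicit Python loops over samples and sensors)
    as an independent oracle for the vectorized path; not for production use.
    """
    if series.n_channels != layout.n_sensors:
        raise ChannelCountError("channel count mismatch")
    n = series.n_samples
    names = list(BASE_VARIABLES)
    channels = {k: np.full(n, np.nan) for k in names}
    valid = {k: np.zeros(n, dtype=bool) for k in names}
    subsets = {
        "CoMXUp": (layout.x, layout.top_mask),
        "CoMXDown": (layout.x, layout.bottom_mask),
        "CoMX": (layout.x, np.ones(layout.n_sensors, bool)),
        "CoMZ": (layout.z, np.ones(layout.n_sensors, bool)),
    }
    for s in range(n):
        for name, (coord, mask) in subsets.items():
            num = 0.0
            den = 0.0
            for i in range(layout.n_sensors):
                if mask[i]:
                    num += series.forces[s, i] * coord[i]
                    den += series.forces[s, i]
            if den > 0:
                channels[name][s] = num / den
                valid[name][s] = True
        top_sum = sum(
            series.forces[s, i]
            for i in range(layout.n_sensors)
            if layout.side[i] == "top"
        )
        bot_sum = sum(
            series.forces[s, i]
            for i in range(layout.n_sensors)
            if layout.side[i] == "bottom"
        )
        channels["MPUp"][s] = top_sum / int(layout.top_mask.sum())
        channels["MPDown"][s] = bot_sum / int(layout.bottom_mask.sum())
        valid["MPUp"][s] = True
        valid["MPDown"][s] = True
    return DerivedSeries(series.timestamps.copy(), channels, valid)
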
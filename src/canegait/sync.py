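"""Alignment of the cane stream with the reference kinematics stream.

Both acquisition chains observe the same physical quantity — the inclination
of the cane with respect to the vertical — through different sensors and on
different clocks and rates (the cane electronics at 50 Hz, the reference
motion-capture stream faster).  The alignment procedure is:

1. normalize both inclination signals to the unit range [0, 1];
2. discard everything before the first and after the last local peak of
   each signal;
3. interpolate the slower (cane) signal onto the reference rate so both have
   the same sampling;
4. shift one signal against the other and keep the shift that maximizes the
   Pearson correlation between them;
5. apply that single shift to all cane-stream timestamps.

The integer-sample argmax is refined by parabolic interpolation of the
correlation around the peak, giving sub-sample lag resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

#: minimum peak prominence, as a fraction of the normalized range, for a
#: local maximum to qualify as a trim bound
PEAK_PROMINENCE_FRACTION = 0.05


class DegenerateSignalError(ValueError):
    """Signal has zero range (constant) and cannot be normalized."""


class InsufficientStructureError(ValueError):
    """Signal lacks the local peaks required for trimming."""


class SyncError(ValueError):
    """Synchronization could not be computed (overlap/undefined correlation)."""


@dataclass(frozen=True)
class SyncResult:
    """Outcome of the two-stream alignment.

    ``lag`` is the shift in seconds to *add* to cane-stream timestamps so
    that both streams agree; ``peak_correlation`` is the Pearson r at the
    best integer shift; ``resampled_length`` the number of common-grid
    samples the cane signal was interpolated onto.
    """

    lag: float
    peak_correlation: float
    resampled_length: int

    def __post_init__(self):
        if not np.isfinite(self.lag):
            raise ValueError("lag must be finite")
        if not -1.0 <= self.peak_correlation <= 1.0 + 1e-12:
            raise ValueError("peak_correlation outside [-1, 1]")


def normalize_unit_range(signal: np.ndarray) -> np.ndarray:
    """Affinely map a signal onto [0, 1] (min -> 0, max -> 1).

    Raises
    ------
    DegenerateSignalError
        If the signal is constant or has fewer than 2 samples.
    """
    y = np.asarray(signal, dtype=float)
    if y.size < 2:
        raise DegenerateSignalError("need >=2 samples to normalize")
    lo, hi = np.min(y), np.max(y)
    if hi == lo:
        raise DegenerateSignalError("constant signal has no unit range")
    return (y - lo) / (hi - lo)


def trim_to_peaks(
    signal: np.ndarray,
    prominence_fraction: float = PEAK_PROMINENCE_FRACTION,
) -> tuple[np.ndarray, int, int]:
    """Trim a signal to the closed span between its first and last local peak.

    A peak is a strict local maximum with prominence at least
    ``prominence_fraction`` of the signal range, so that noise wiggles do
    not define the trim bounds.  Returns (segment, start_index, end_index),
    bounds inclusive.

    Raises
    ------
    InsufficientStructureError
        If fewer than 2 qualifying peaks exist.
    """
    y = np.asarray(signal, dtype=float)
    rng = float(np.max(y) - np.min(y)) if y.size else 0.0
    if rng == 0.0:
        raise InsufficientStructureError("flat signal has no local peaks")
    peaks, _ = find_peaks(y, prominence=prominence_fraction * rng)
    if len(peaks) < 2:
        raise InsufficientStructureError(
            f"need >=2 local peaks to trim, found {len(peaks)}"
        )
    start, end = int(peaks[0]), int(peaks[-1])
    return y[start : end + 1], start, end


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def synchronize(
    cane_time: np.ndarray,
    cane_angle: np.ndarray,
    ref_time: np.ndarray,
    ref_angle: np.ndarray,
    max_lag: float = 5.0,
    min_overlap: float = 0.5,
    refine: bool = True,
) -> SyncResult:
    """Estimate the lag between the cane and reference streams.

    Both inclination signals are normalized to [0, 1] and trimmed to their
    first/last local peaks; the cane segment is linearly interpolated onto
    the reference sampling grid; integer-sample shifts within ``max_lag``
    seconds of the peak-to-peak coarse alignment are scanned for the maximum
    Pearson correlation (ties broken toward the smallest absolute lag), and
    the argmax is refined parabolically.

    Returns the lag to add to cane-stream timestamps.

    Raises
    ------
    DegenerateSignalError, InsufficientStructureError
        Propagated from normalization/trimming.
    SyncError
        If no shift leaves at least ``min_overlap`` of the shorter signal
        overlapping, or every correlation is undefined.
    """
    cane_time = np.asarray(cane_time, dtype=float)
    ref_time = np.asarray(ref_time, dtype=float)
    cane_n = normalize_unit_range(cane_angle)
    ref_n = normalize_unit_range(ref_angle)

    cane_seg, c0, c1 = trim_to_peaks(cane_n)
    ref_seg, r0, r1 = trim_to_peaks(ref_n)
    t_c = cane_time[c0 : c1 + 1]
    t_r = ref_time[r0 : r1 + 1]

    dt = float(np.median(np.diff(t_r)))
    # uniform common-rate grids, each anchored at its own trim start
    grid_r = t_r[0] + dt * np.arange(int(np.floor((t_r[-1] - t_r[0]) / dt)) + 1)
    grid_c = t_c[0] + dt * np.arange(int(np.floor((t_c[-1] - t_c[0]) / dt)) + 1)
    ref_g = np.interp(grid_r, t_r, ref_seg)
    cane_g = np.interp(grid_c, t_c, cane_seg)

    coarse = float(t_r[0] - t_c[0])
    n_r, n_c = len(ref_g), len(cane_g)
    min_m = int(np.ceil(min_overlap * min(n_r, n_c)))
    s_max = int(round(max_lag / dt))

    shifts = np.arange(-s_max, s_max + 1)
    corrs = np.full(len(shifts), np.nan)
    for j, s in enumerate(shifts):
        if s >= 0:
            m = min(n_r - s, n_c)
            if m < max(min_m, 2):
                continue
            corrs[j] = _pearson(ref_g[s : s + m], cane_g[:m])
        else:
            m = min(n_r, n_c + s)
            if m < max(min_m, 2):
                continue
            corrs[j] = _pearson(ref_g[:m], cane_g[-s : -s + m])
    if np.all(np.isnan(corrs)):
        raise SyncError("no admissible shift with sufficient overlap")

    rmax = np.nanmax(corrs)
    candidates = np.flatnonzero(corrs >= rmax - 1e-12)
    # tie-break toward the smallest |total lag|
    j_best = candidates[np.argmin(np.abs(coarse + shifts[candidates] * dt))]
    lag = coarse + shifts[j_best] * dt

    if refine and 0 < j_best < len(shifts) - 1:
        rm, r_0, rp = corrs[j_best - 1], corrs[j_best], corrs[j_best + 1]
        denom = rm - 2.0 * r_0 + rp
        if np.isfinite(rm) and np.isfinite(rp) and denom < 0:
            delta = 0.5 * (rm - rp) / denom
            lag += float(np.clip(delta, -1.0, 1.0)) * dt

    return SyncResult(
        lag=float(lag),
        peak_correlation=float(min(corrs[j_best], 1.0)),
        resampled_length=int(n_c),
    )


def apply_lag(timestamps: np.ndarray, result: SyncResult) -> np.ndarray:
    """Shift cane-stream timestamps onto the reference clock."""
    return np.asarray(timestamps, dtype=float) + result.lag
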
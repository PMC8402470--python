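"""Geometry of the FSR array on the cane handle.

The handle carries 16 force-sensing resistors in the sagittal plane: 10 on
the top side (under the palm) and 6 on the bottom side (under the fingers).
Coordinates are expressed in millimetres in a local frame whose z-axis is
aligned with the cane shaft.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_UP = 10
N_DOWN = 6
N_SENSORS = N_UP + N_DOWN

#: (sensor_id, x_mm, z_mm, side) for the reference handle.  Sensors 1-10 sit
#: on the top side, 11-16 on the bottom side.
_DEFAULT_LAYOUT = (
    (1, -15.21, 85.05, "top"),
    (2, -5.29, 84.95, "top"),
    (3, 4.71, 85.22, "top"),
    (4, 14.58, 85.61, "top"),
    (5, 24.44, 86.72, "top"),
    (6, 34.50, 87.72, "top"),
    (7, 44.60, 88.19, "top"),
    (8, 54.71, 88.10, "top"),
    (9, 64.80, 87.47, "top"),
    (10, 74.86, 86.27, "top"),
    (11, -19.66, 49.89, "bottom"),
    (12, 19.12, 53.30, "bottom"),
    (13, 30.40, 54.54, "bottom"),
    (14, 42.10, 54.85, "bottom"),
    (15, 53.15, 54.74, "bottom"),
    (16, 64.65, 54.08, "bottom"),
)


class LayoutError(ValueError):
    """Raised when a handle layout violates the 10-top/6-bottom contract."""


@dataclass(frozen=True)
class HandleLayout:
    """Sensor coordinates and the top/bottom partition of the handle.

    Parameters
    ----------
    sensor_id : array of int
        Unique sensor identifiers, 1..16 for the reference handle.
    x, z : array of float
        Sensor coordinates in millimetres in the handle-local sagittal frame.
    side : array of str
        ``"top"`` or ``"bottom"`` per sensor.
    """

    sensor_id: np.ndarray
    x: np.ndarray
    z: np.ndarray
    side: np.ndarray
    _order: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        sid = np.asarray(self.sensor_id, dtype=int)
        x = np.asarray(self.x, dtype=float)
        z = np.asarray(self.z, dtype=float)
        side = np.asarray(self.side, dtype=object)
        if not (len(sid) == len(x) == len(z) == len(side)):
            raise LayoutError("layout columns have mismatched lengths")
        if len(np.unique(sid)) != len(sid):
            raise LayoutError("duplicate sensor ids in layout")
        if not (np.isfinite(x).all() and np.isfinite(z).all()):
            raise LayoutError("non-finite sensor coordinates")
        bad = set(side) - {"top", "bottom"}
        if bad:
            raise LayoutError(f"unknown side labels: {sorted(bad)}")
        n_top = int(np.sum(side == "top"))
        n_bottom = int(np.sum(side == "bottom"))
        if n_top != N_UP or n_bottom != N_DOWN:
            raise LayoutError(
                f"expected {N_UP} top and {N_DOWN} bottom sensors, "
                f"got {n_top} top and {n_bottom} bottom"
            )
        # canonical storage order: ascending sensor id
        order = np.argsort(sid)
        object.__setattr__(self, "sensor_id", sid[order])
        object.__setattr__(self, "x", x[order])
        object.__setattr__(self, "z", z[order])
        object.__setattr__(self, "side", side[order])
        object.__setattr__(self, "_order", order)

    @property
    def n_sensors(self) -> int:
        return len(self.sensor_id)

    @property
    def top_mask(self) -> np.ndarray:
        return self.side == "top"

    @property
    def bottom_mask(self) -> np.ndarray:
        return self.side == "bottom"

    def coordinates(self, sensor_id: int) -> tuple[float, float]:
        """Return (x, z) in millimetres of one sensor."""
        idx = np.flatnonzero(self.sensor_id == sensor_id)
        if len(idx) == 0:
            raise KeyError(f"no sensor with id {sensor_id}")
        return float(self.x[idx[0]]), float(self.z[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sensor_id": self.sensor_id,
                "x_mm": self.x,
                "z_mm": self.z,
                "side": self.side,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HandleLayout":
        required = {"sensor_id", "x_mm", "z_mm", "side"}
        missing = required - set(df.columns)
        if missing:
            raise LayoutError(f"layout table missing columns: {sorted(missing)}")
        return cls(
            sensor_id=df["sensor_id"].to_numpy(),
            x=df["x_mm"].to_numpy(),
            z=df["z_mm"].to_numpy(),
            side=df["side"].to_numpy(),
        )


def load_default_layout() -> HandleLayout:
    """Return the reference 16-sensor handle layout.

    Ten sensors (ids 1-10) lie on the top side of the handle and six
    (ids 11-16) on the bottom side; coordinates are millimetres in the
    handle-local sagittal frame.
    """
    ids, xs, zs, sides = zip(*_DEFAULT_LAYOUT)
    return HandleLayout(
        sensor_id=np.array(ids),
        x=np.array(xs),
        z=np.array(zs),
        side=np.array(sides, dtype=object),
    )
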
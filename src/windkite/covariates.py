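"""Physical covariate layers: orographic and thermal uplift, terrain
derivatives, 500 m grid aggregation, and time-matching of wind records.

Orographic uplift follows the standard terrain-lift decomposition: the wind
speed is projected onto the upslope direction and tilted by the slope angle,

    w_oro = v * sin(slope) * max(0, cos(aspect - wind_from)),

where ``aspect`` is the downslope-facing compass direction, so a slope whose
aspect equals the wind FROM-direction faces squarely into the wind.  Lee-side
(negative-cosine) flow produces no lift.  Thermal uplift uses the convective
velocity scale w* = (g z_i dT / T_ref)^(1/3) driven by the surface-temperature
excess over a reference temperature, with boundary-layer height z_i fixed
(default 1000 m); it is treated as static per grid cell, reflecting the low
midday temporal variability of summer convection at each turbine site.
Rotor-wake turbulence is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

GRAVITY = 9.81  # m/s^2
DEFAULT_BOUNDARY_LAYER_M = 1000.0
WIND_STALENESS_LIMIT_S = 3600.0  # older matches flag the covariate missing

__all__ = [
    "TerrainCell",
    "UpliftEstimate",
    "orographic_uplift",
    "thermal_uplift",
    "aspect_slope_from_grid",
    "aggregate_to_grid",
    "match_wind",
    "WIND_STALENESS_LIMIT_S",
]


@dataclass(frozen=True)
class TerrainCell:
    """One terrain grid cell: aspect/slope in degrees, optional surface temp (K)."""

    cell_id: str
    lon: float
    lat: float
    aspect: float
    slope: float
    surface_temp: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.slope < 90.0:
            raise ValueError(f"slope out of range [0, 90): {self.slope}")
        if not 0.0 <= self.aspect < 360.0:
            raise ValueError(f"aspect out of range [0, 360): {self.aspect}")


@dataclass(frozen=True)
class UpliftEstimate:
    """Uplift components (m/s) at a cell; orographic is time-varying."""

    cell_id: str
    orographic: float
    thermal: float
    timestamp: Optional[np.datetime64] = None

    def __post_init__(self) -> None:
        if self.orographic < 0.0 or self.thermal < 0.0:
            raise ValueError("uplift components must be non-negative")


def orographic_uplift(wind_speed, wind_direction_from, aspect, slope):
    """Orographic uplift velocity (m/s), zero on flat ground or the lee side."""
    ws = np.asarray(wind_speed, dtype=float)
    if np.any(ws < 0.0):
        raise ValueError("wind_speed must be >= 0")
    sl = np.asarray(slope, dtype=float)
    if np.any((sl < 0.0) | (sl >= 90.0)):
        raise ValueError("slope must lie in [0, 90) degrees")
    exposure = np.cos(np.radians(np.asarray(aspect, dtype=float)
                                 - np.asarray(wind_direction_from, dtype=float)))
    w = ws * np.sin(np.radians(sl)) * np.maximum(0.0, exposure)
    return float(w) if w.ndim == 0 else w


def thermal_uplift(surface_temp, reference_temp,
                   boundary_layer_height: float = DEFAULT_BOUNDARY_LAYER_M):
    """Convective velocity scale (m/s) from the surface-temperature excess.

    Zero when the surface is no warmer than the reference; monotone
    increasing in surface temperature.
    """
    ts = np.asarray(surface_temp, dtype=float)
    tr = np.asarray(reference_temp, dtype=float)
    if np.any(ts <= 0.0) or np.any(tr <= 0.0):
        raise ValueError("temperatures must be positive (Kelvin)")
    excess = np.maximum(0.0, ts - tr)
    w = np.cbrt(GRAVITY * boundary_layer_height * excess / tr)
    return float(w) if w.ndim == 0 else w


def aspect_slope_from_grid(elevation: np.ndarray, cell_size_m: float
                           ) -> Tuple[np.ndarray, np.ndarray]:
    """Slope and aspect (degrees) from an elevation grid by Horn's method.

    ``elevation[i, j]`` has row index i increasing northward and column index
    j increasing eastward; ``cell_size_m`` is the grid spacing in meters.
    Returns ``(aspect, slope)`` arrays; border cells are NaN (Horn's
    eight-neighbour stencil is undefined there), as is the aspect of flat
    cells.  Aspect is the downslope-facing compass direction.
    """
    z = np.asarray(elevation, dtype=float)
    if z.ndim != 2 or z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("elevation grid must be at least 3 x 3")
    if not cell_size_m > 0:
        raise ValueError("cell_size_m must be > 0")

    # Horn 1981 third-order finite differences on the interior.
    nw, n_, ne = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    dz_dx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8.0 * cell_size_m)
    dz_dy = ((ne + 2 * n_ + nw) - (se + 2 * s_ + sw)) / (8.0 * cell_size_m)

    grad = np.hypot(dz_dx, dz_dy)
    slope_int = np.degrees(np.arctan(grad))
    # Downslope direction is -grad; atan2(east, north) gives the compass angle.
    aspect_int = np.mod(np.degrees(np.arctan2(-dz_dx, -dz_dy)), 360.0)
    aspect_int = np.where(grad == 0.0, np.nan, aspect_int)

    aspect = np.full(z.shape, np.nan)
    slope = np.full(z.shape, np.nan)
    aspect[1:-1, 1:-1] = aspect_int
    slope[1:-1, 1:-1] = slope_int
    return aspect, slope


def aggregate_to_grid(x_m: Sequence[float], y_m: Sequence[float],
                      values: Sequence[float], cell_size_m: float = 500.0
                      ) -> pd.DataFrame:
    """Mean of point values per square grid cell (default 500 x 500 m).

    Cell assignment is by floor division of the metric coordinates; the
    returned frame has one row per non-empty cell with the cell indices, cell
    center coordinates, the mean value and the point count.
    """
    if not cell_size_m > 0:
        raise ValueError("cell_size_m must be > 0")
    x = np.asarray(x_m, dtype=float)
    y = np.asarray(y_m, dtype=float)
    v = np.asarray(values, dtype=float)
    if not (x.shape == y.shape == v.shape):
        raise ValueError("x, y and values must have equal length")
    if x.size == 0:
        return pd.DataFrame(columns=["ix", "iy", "x_center", "y_center", "mean", "count"])
    ix = np.floor(x / cell_size_m).astype(int)
    iy = np.floor(y / cell_size_m).astype(int)
    df = pd.DataFrame({"ix": ix, "iy": iy, "value": v})
    out = df.groupby(["ix", "iy"], as_index=False)["value"].agg(["mean", "count"])
    out["x_center"] = (out["ix"] + 0.5) * cell_size_m
    out["y_center"] = (out["iy"] + 0.5) * cell_size_m
    return out[["ix", "iy", "x_center", "y_center", "mean", "count"]]


def match_wind(timestamps, wind: pd.DataFrame,
               staleness_limit_s: float = WIND_STALENESS_LIMIT_S
               ) -> pd.DataFrame:
    """Match each query timestamp to the nearest wind record in time.

    ``wind`` must be sorted by its ``timestamp`` column and carry
    ``wind_direction_deg`` and ``wind_speed_ms``.  Ties are broken toward the
    earlier record.  Matches farther than ``staleness_limit_s`` (default one
    hour, generous against the 10-minute station cadence) are flagged
    ``wind_missing`` and their wind fields set to NaN.
    """
    if len(wind) == 0:
        raise ValueError("wind series is empty")
    wt = pd.to_datetime(wind["timestamp"]).to_numpy(dtype="datetime64[ns]")
    if np.any(np.diff(wt) < np.timedelta64(0, "ns")):
        raise ValueError("wind series must be sorted by timestamp")
    qt = pd.to_datetime(pd.Series(timestamps)).to_numpy(dtype="datetime64[ns]")

    idx_right = np.searchsorted(wt, qt, side="left")
    idx_left = np.clip(idx_right - 1, 0, len(wt) - 1)
    idx_right = np.clip(idx_right, 0, len(wt) - 1)
    dt_left = np.abs((qt - wt[idx_left]) / np.timedelta64(1, "s"))
    dt_right = np.abs((wt[idx_right] - qt) / np.timedelta64(1, "s"))
    # ties (dt_left == dt_right) resolve to the earlier record
    take_left = dt_left <= dt_right
    idx = np.where(take_left, idx_left, idx_right)
    gap = np.where(take_left, dt_left, dt_right)

    out = pd.DataFrame({
        "wind_direction_deg": wind["wind_direction_deg"].to_numpy(dtype=float)[idx],
        "wind_speed_ms": wind["wind_speed_ms"].to_numpy(dtype=float)[idx],
        "wind_gap_s": gap,
        "wind_missing": gap > staleness_limit_s,
    })
    out.loc[out["wind_missing"], ["wind_direction_deg", "wind_speed_ms"]] = np.nan
    return out
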
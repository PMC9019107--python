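"""Geometric and kinematic primitives for turbine-avoidance analysis.

All public functions take and return angles in **degrees** (radians are used
only internally).  Headings, bearings and wind directions are compass angles,
clockwise from true north; wind directions follow the meteorological
convention (the direction the wind blows *from*).  Distances and bearings are
great-circle quantities on a sphere of radius 6 371 000 m — at the sub-2 km
ranges relevant here the spherical/planar discrepancy is far below GPS noise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np

EARTH_RADIUS_M = 6_371_000.0

__all__ = [
    "EARTH_RADIUS_M",
    "TrackPoint",
    "Turbine",
    "WindRecord",
    "HeightClass",
    "great_circle_distance",
    "initial_bearing",
    "angular_deviation",
    "facing_indicator",
    "wind_component_towards",
    "max_turbine_height",
    "height_class",
]


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrackPoint:
    """A single GPS fix with kinematics.

    ``height_agl`` is height above ground in meters; ``heading`` is the
    direction of travel in degrees clockwise from true north, in [0, 360).
    """

    bird_id: str
    timestamp: np.datetime64
    lon: float
    lat: float
    height_agl: float
    ground_speed: float
    heading: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"lat out of range [-90, 90]: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"lon out of range [-180, 180]: {self.lon}")
        if not 0.0 <= self.heading < 360.0:
            raise ValueError(f"heading out of range [0, 360): {self.heading}")
        if self.ground_speed < 0.0:
            raise ValueError(f"ground_speed must be >= 0: {self.ground_speed}")


@dataclass(frozen=True)
class Turbine:
    """A wind turbine: location plus rotor dimensions (meters)."""

    turbine_id: str
    lon: float
    lat: float
    rotor_diameter: float
    hub_height: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.rotor_diameter > 0.0:
            raise ValueError(
                f"rotor_diameter must be > 0: {self.rotor_diameter}"
            )

    @property
    def max_height(self) -> float:
        """Top of the rotor-swept zone above ground."""
        return max_turbine_height(self.rotor_diameter, self.hub_height)


@dataclass(frozen=True)
class WindRecord:
    """A timestamped wind observation (meteorological FROM convention)."""

    timestamp: np.datetime64
    direction_from: float
    speed: float

    def __post_init__(self) -> None:
        if self.speed < 0.0:
            raise ValueError(f"wind speed must be >= 0: {self.speed}")
        if not 0.0 <= self.direction_from < 360.0:
            raise ValueError(
                f"direction_from out of range [0, 360): {self.direction_from}"
            )


class HeightClass(enum.Enum):
    """Flight height relative to the maximum turbine height H.

    LOW: up to H (the rotor-swept, collision-risk band);
    MEDIUM: above H up to 2H; HIGH: above 2H.
    """

    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# ---------------------------------------------------------------------------
# Angular / spherical primitives
# ---------------------------------------------------------------------------


def _check_finite(name: str, *values) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite value in '{name}'")


def great_circle_distance(lat1, lon1, lat2, lon2):
    """Haversine great-circle distance in meters (vectorized).

    Symmetric, non-negative, and zero iff the points coincide.
    """
    _check_finite("lat1", lat1)
    _check_finite("lon1", lon1)
    _check_finite("lat2", lat2)
    _check_finite("lon2", lon2)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return EARTH_RADIUS_M * 2.0 * np.arcsin(np.sqrt(a))


def initial_bearing(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing from point 1 to point 2, degrees in [0, 360).

    Undefined (raises ``ValueError``) for identical points in the scalar case.
    """
    _check_finite("lat1", lat1)
    _check_finite("lon1", lon1)
    _check_finite("lat2", lat2)
    _check_finite("lon2", lon2)
    scalar = np.isscalar(lat1) and np.isscalar(lon1) and np.isscalar(lat2) and np.isscalar(lon2)
    if scalar and lat1 == lat2 and lon1 == lon2:
        raise ValueError("bearing undefined for identical points")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dlam = np.radians(np.asarray(lon2) - np.asarray(lon1))
    x = np.sin(dlam) * np.cos(phi2)
    y = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    brng = np.degrees(np.arctan2(x, y))
    return np.mod(brng, 360.0)


def angular_deviation(heading, bearing):
    """Minimal absolute circular difference between two compass angles.

    Returns degrees in [0, 180]; symmetric in its arguments and invariant to
    adding multiples of 360 to either.
    """
    _check_finite("heading", heading)
    _check_finite("bearing", bearing)
    d = np.mod(np.asarray(heading, dtype=float) - np.asarray(bearing, dtype=float), 360.0)
    out = np.where(d > 180.0, 360.0 - d, d)
    return float(out) if out.ndim == 0 else out


def facing_indicator(deviation):
    """Binary facing response: 1 iff the heading deviates < 60 degrees from the
    bearing to the nearest turbine (strict inequality), else 0.

    Under uniformly random headings the expectation is 120/360 = 1/3.
    """
    dev = np.asarray(deviation, dtype=float)
    if np.any(dev < 0.0) or np.any(dev > 180.0):
        raise ValueError("deviation must lie in [0, 180] degrees")
    out = (dev < 60.0).astype(int)
    return int(out) if out.ndim == 0 else out


def wind_component_towards(speed, direction_from, bearing_to_turbine):
    """Signed wind component (m/s) along the bearing to the turbine.

    The meteorological FROM direction is converted to the blowing-TO direction
    (+180 degrees) before projecting.  Positive values mean the wind pushes the
    bird toward the turbine; |component| <= speed always.
    """
    spd = np.asarray(speed, dtype=float)
    if np.any(spd < 0.0):
        raise ValueError("wind speed must be >= 0")
    _check_finite("direction_from", direction_from)
    _check_finite("bearing_to_turbine", bearing_to_turbine)
    blow_to = np.asarray(direction_from, dtype=float) + 180.0
    comp = spd * np.cos(np.radians(blow_to - np.asarray(bearing_to_turbine, dtype=float)))
    return float(comp) if comp.ndim == 0 else comp


def max_turbine_height(rotor_diameter, hub_height=None):
    """Top of the rotor-swept zone: hub height plus rotor radius.

    When hub height is unknown it is taken equal to the rotor diameter
    (observed to be similar in length for the turbines of this region),
    so the maximum height defaults to 1.5 x rotor diameter.
    """
    rd = np.asarray(rotor_diameter, dtype=float)
    if np.any(rd <= 0.0):
        raise ValueError("rotor_diameter must be > 0")
    if hub_height is None:
        out = 1.5 * rd
    else:
        hh = np.asarray(hub_height, dtype=float)
        out = np.where(np.isnan(hh), 1.5 * rd, hh + rd / 2.0)
    return float(out) if np.ndim(out) == 0 else out


def height_class(height_agl, max_height):
    """Classify flight height against the maximum turbine height H.

    LOW iff height <= H; MEDIUM iff H < height <= 2H; HIGH iff height > 2H.
    Boundaries are inclusive downward ("up to" H / 2H).  Negative heights
    (GPS error) are mapped to LOW; callers count them separately.
    """
    H = np.asarray(max_height, dtype=float)
    if np.any(H <= 0.0):
        raise ValueError("max turbine height must be > 0")
    h = np.asarray(height_agl, dtype=float)
    if np.ndim(h) == 0 and np.ndim(H) == 0:
        if h <= H:
            return HeightClass.LOW
        if h <= 2.0 * H:
            return HeightClass.MEDIUM
        return HeightClass.HIGH
    out = np.where(h <= H, HeightClass.LOW.value,
                   np.where(h <= 2.0 * H, HeightClass.MEDIUM.value, HeightClass.HIGH.value))
    return out
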
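"""Spatial reasoning for the enforced-detour paradigm.

A bee trained to a feeder holds a *food vector* (distance + compass
bearing).  When the first leg of her outbound flight is forced through a
detour tunnel, the remembered vector no longer points at the feeder from
the detour exit.  Two competing predictions describe the corrective turn
she should make on release:

* **shortcut**: turn onto the straight line from the detour exit to the
  *virtual feeder* — the point the food vector designates, displaced by
  the detour (requires combining the vector with path integration);
* **bearing resume**: simply turn back onto the original compass bearing
  of the food vector (direction only, no location).

All angles here are degrees.  The local frame puts the detour entrance
at the origin with +x along the hive→food bearing; angles in this frame
are counterclockwise-positive, wrapped to (-180, 180].  Geographic
azimuths (solar, comb-decoded bearings) are clockwise from North in
[0, 360).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "DetourConfig",
    "Point2D",
    "SolarContext",
    "wrap_angle",
    "detour_exit_position",
    "virtual_feeder_position",
    "shortcut_turn",
    "bearing_resume_turn",
    "solar_azimuth",
    "comb_to_geographic",
    "geographic_to_comb",
]


def wrap_angle(raw):
    """Wrap an angle in degrees to the half-open interval (-180, 180].

    Accepts scalars or array-likes; NaN/inf raise ``ValueError``.
    """
    arr = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("angle must be finite")
    wrapped = 180.0 - np.mod(180.0 - arr, 360.0)
    if arr.ndim == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class Point2D:
    """Position in metres in the local detour frame (+x = food bearing)."""

    x: float
    y: float

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("coordinates must be finite")


@dataclass
class DetourConfig:
    """Geometry of hive, food vector, detour tunnel and recording setup.

    Defaults follow the training condition: a 12.4 m food vector, a 2 m
    detour, angle boundaries at 0.22/0.44/0.66 m from the detour exit,
    and a 60 Hz camera viewing a 1.56 m x 0.84 m horizontal plane.
    """

    food_distance: float = 12.4
    food_bearing: float = 0.0  # geographic azimuth of hive->food, deg
    detour_length: float = 2.0
    detour_relative_angle: float = 45.0  # deg relative to food bearing, CCW+
    boundary_radii: tuple = (0.22, 0.44, 0.66)
    hive_lat: float = 52.46
    hive_lon: float = 13.30
    fov_length: float = 1.56
    fov_width: float = 0.84
    frame_rate: float = 60.0

    def __post_init__(self):
        if not self.food_distance > self.detour_length > 0:
            raise ValueError("require food_distance > detour_length > 0")
        radii = tuple(float(r) for r in self.boundary_radii)
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("boundary_radii must be strictly increasing")
        fov_diag = math.hypot(self.fov_length, self.fov_width)
        if radii and radii[-1] >= fov_diag:
            raise ValueError("boundary radii must fit inside the field of view")
        if abs(self.detour_relative_angle) > 90:
            raise ValueError("|detour_relative_angle| must be <= 90 deg")
        self.boundary_radii = radii

    @classmethod
    def from_yaml(cls, path) -> "DetourConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in raw.items() if k in known})

    def to_yaml(self, path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        data["boundary_radii"] = list(data["boundary_radii"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def detour_exit_position(cfg: DetourConfig) -> Point2D:
    """Detour exit in the local frame (entrance at origin, +x food bearing)."""
    theta = math.radians(cfg.detour_relative_angle)
    return Point2D(cfg.detour_length * math.cos(theta),
                   cfg.detour_length * math.sin(theta))


def virtual_feeder_position(cfg: DetourConfig) -> Point2D:
    """The virtual feeder: food_distance along +x from the detour entrance.

    The release point at the detour entrance stands in for the hive, so
    the remembered vector is replayed from there.
    """
    return Point2D(cfg.food_distance, 0.0)


def shortcut_turn(cfg: DetourConfig) -> float:
    """Signed turn from the detour heading onto the exit->virtual-feeder line.

    Positive is counterclockwise (leftward).  For the canonical +45 deg
    detour of 2 m against a 12.4 m food vector this is -52.33 deg.
    """
    exit_p = detour_exit_position(cfg)
    feeder = virtual_feeder_position(cfg)
    dx, dy = feeder.x - exit_p.x, feeder.y - exit_p.y
    if math.hypot(dx, dy) < 1e-12:
        raise ValueError("detour exit coincides with the virtual feeder; "
                         "shortcut direction undefined")
    bearing = math.degrees(math.atan2(dy, dx))
    return wrap_angle(bearing - cfg.detour_relative_angle)


def bearing_resume_turn(cfg: DetourConfig) -> float:
    """Turn that restores the original food-vector compass bearing."""
    return wrap_angle(-cfg.detour_relative_angle)


# --------------------------------------------------------------------------
# Solar position (NOAA-style mid-accuracy algorithm)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SolarContext:
    """Time and place used to convert comb angles to geographic bearings."""

    timestamp: datetime
    lat: float
    lon: float

    def __post_init__(self):
        ts = self.timestamp
        if ts.tzinfo is None:
            raise ValueError("timestamp must be timezone-aware")
        year = ts.astimezone(timezone.utc).year
        if not 1900 <= year <= 2100:
            raise ValueError("timestamp outside supported range 1900-2100")

    @property
    def azimuth(self) -> float:
        return solar_azimuth(self)


def _julian_day(ts: datetime) -> float:
    ts = ts.astimezone(timezone.utc)
    y, m = ts.year, ts.month
    d = (ts.day + ts.hour / 24 + ts.minute / 1440 + ts.second / 86400
         + ts.microsecond / 86_400_000_000)
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return int(365.25 * (y + 4716)) + int(30.6001 * (m + 1)) + d + b - 1524.5


def solar_azimuth(ctx: SolarContext) -> float:
    """Geographic azimuth of the sun, degrees clockwise from North.

    NOAA's mid-accuracy solar position algorithm (the one behind their
    solar calculator): better than ~0.2 deg over 1900-2100, well below
    the behavioural scatter in flight and dance angles.
    """
    jd = _julian_day(ctx.timestamp)
    t = (jd - 2451545.0) / 36525.0  # Julian centuries from J2000

    # mean solar longitude / anomaly, equation of center -> true longitude
    l0 = (280.46646 + t * (36000.76983 + 0.0003032 * t)) % 360.0
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    mr = math.radians(m)
    c = (math.sin(mr) * (1.914602 - t * (0.004817 + 0.000014 * t))
         + math.sin(2 * mr) * (0.019993 - 0.000101 * t)
         + math.sin(3 * mr) * 0.000289)
    true_long = l0 + c
    omega = 125.04 - 1934.136 * t
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(omega))

    # obliquity (corrected) and declination
    e0 = 23 + (26 + (21.448 - t * (46.8150 + t * (0.00059 - 0.001813 * t))) / 60) / 60
    eps = e0 + 0.00256 * math.cos(math.radians(omega))
    eps_r = math.radians(eps)
    decl = math.asin(math.sin(eps_r) * math.sin(math.radians(app_long)))

    # equation of time (minutes)
    y = math.tan(eps_r / 2) ** 2
    l0r = math.radians(l0)
    ecc = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    eot = 4 * math.degrees(
        y * math.sin(2 * l0r)
        - 2 * ecc * math.sin(mr)
        + 4 * ecc * y * math.sin(mr) * math.cos(2 * l0r)
        - 0.5 * y * y * math.sin(4 * l0r)
        - 1.25 * ecc * ecc * math.sin(2 * mr)
    )

    ts = ctx.timestamp.astimezone(timezone.utc)
    minutes_utc = ts.hour * 60 + ts.minute + ts.second / 60 + ts.microsecond / 6e7
    true_solar_min = (minutes_utc + eot + 4 * ctx.lon) % 1440
    ha = true_solar_min / 4 - 180  # hour angle, deg; negative before noon
    if ha < -180:
        ha += 360

    lat_r = math.radians(ctx.lat)
    ha_r = math.radians(ha)
    cos_zen = (math.sin(lat_r) * math.sin(decl)
               + math.cos(lat_r) * math.cos(decl) * math.cos(ha_r))
    cos_zen = min(1.0, max(-1.0, cos_zen))
    zen = math.acos(cos_zen)
    sin_zen = math.sin(zen)
    if sin_zen < 1e-9:  # sun at zenith/nadir: azimuth degenerate
        return 180.0
    cos_az = (math.sin(lat_r) * cos_zen - math.sin(decl)) / (math.cos(lat_r) * sin_zen)
    cos_az = min(1.0, max(-1.0, cos_az))
    az = math.degrees(math.acos(cos_az))
    if ha > 0:
        az = 180.0 + az  # afternoon: sun west of the meridian
    else:
        az = 180.0 - az  # morning: sun east of the meridian
    return az % 360.0


def comb_to_geographic(comb_angle: float, ctx: SolarContext) -> float:
    """Map a waggle angle on the comb to a geographic bearing.

    Straight-up waggling means "toward the solar azimuth"; the comb
    angle is measured clockwise from gravity-up and adds clockwise to
    the azimuth.  Result in [0, 360).
    """
    return (solar_azimuth(ctx) + comb_angle) % 360.0


def geographic_to_comb(bearing: float, ctx: SolarContext) -> float:
    """Inverse of :func:`comb_to_geographic`; returns (-180, 180]."""
    return wrap_angle(bearing - solar_azimuth(ctx))
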
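"""Cylinder geometry for rotor-swept zones and curtailment volumes.

A turbine's rotor-swept zone (RSZ) is modelled as a vertical cylinder of
air: radius equal to the rotor radius (optionally buffered), altitude band
between the minimum and maximum blade-tip heights.  Informed curtailment
uses two further, larger cylinders centred on the hub: an inner cylinder
inside which curtailment is always ordered, and an outer cylinder that
gates whether curtailment is considered at all.  All volumes are
yaw-independent cylinders; positions are handled in a local east-north-up
(ENU) tangent plane in metres.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EARTH_RADIUS_M",
    "TurbineSpec",
    "ZoneCylinder",
    "CurtailmentCriteria",
    "enu_project",
    "enu_unproject",
    "min_blade_height",
    "build_zones",
    "point_in_cylinder",
    "ray_cylinder_entry_time",
]

EARTH_RADIUS_M = 6_371_000.0

log = logging.getLogger(__name__)

_warned_dimensions: set[tuple] = set()


@dataclass(frozen=True)
class TurbineSpec:
    """Physical and locational description of one turbine.

    Heights are metres above the turbine's local ground; ``ground_elevation``
    (metres above sea level) is only used when ingesting altitude-above-sea-
    level track data.
    """

    turbine_id: str
    model_name: str
    lat: float
    lon: float
    rotor_diameter: float
    hub_height: float
    max_blade_height: float
    ground_elevation: float = 0.0

    def __post_init__(self) -> None:
        if not self.rotor_diameter > 0:
            raise ValueError(f"{self.turbine_id}: rotor_diameter must be > 0")
        if not self.hub_height > self.rotor_diameter / 2:
            raise ValueError(
                f"{self.turbine_id}: hub_height must exceed the rotor radius"
            )
        expected = self.hub_height + self.rotor_diameter / 2
        if abs(self.max_blade_height - expected) > 0.01:
            # Manufacturer-reported tip heights routinely disagree with
            # hub + rotor/2 by up to ~1 m; the reported value wins.  Warn
            # once per distinct dimension combination, not per turbine.
            key = (self.rotor_diameter, self.hub_height, self.max_blade_height)
            if key not in _warned_dimensions:
                _warned_dimensions.add(key)
                log.warning(
                    "%s: max_blade_height %.2f differs from hub + rotor/2 = %.2f "
                    "(reported value kept)",
                    self.turbine_id,
                    self.max_blade_height,
                    expected,
                )


@dataclass(frozen=True)
class ZoneCylinder:
    """A vertical cylinder: centre axis in ENU metres, closed altitude band."""

    center_xy: tuple[float, float]
    radius: float
    z_min: float
    z_max: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("cylinder radius must be > 0")
        if not (self.z_max > self.z_min >= 0):
            raise ValueError("cylinder must satisfy z_max > z_min >= 0")


@dataclass(frozen=True)
class CurtailmentCriteria:
    """Facility-wide curtailment thresholds.

    Defaults are the post-August-2018 operating values at the study
    facility: inner/outer cylinder radii 150/350 m, heights 200/400 m
    (centred on the hub, clipped at ground), time-to-collision threshold
    10 s, eagle-classification confidence gate 0.90.
    """

    inner_radius: float = 150.0
    outer_radius: float = 350.0
    inner_height: float = 200.0
    outer_height: float = 400.0
    time_to_collision_threshold: float = 10.0
    confidence_threshold: float = 0.90
    rsz_buffer: float = 0.0

    def __post_init__(self) -> None:
        if not self.outer_radius > self.inner_radius > 0:
            raise ValueError("need outer_radius > inner_radius > 0")
        if not self.outer_height > self.inner_height > 0:
            raise ValueError("need outer_height > inner_height > 0")
        if self.time_to_collision_threshold <= 0:
            raise ValueError("time_to_collision_threshold must be > 0")
        if not 0 <= self.confidence_threshold <= 1:
            raise ValueError("confidence_threshold must be in [0, 1]")
        if self.rsz_buffer < 0:
            raise ValueError("rsz_buffer must be >= 0")


def enu_project(lat, lon, ref_lat: float, ref_lon: float):
    """Project geographic coordinates to a local ENU tangent plane.

    Equirectangular projection about (ref_lat, ref_lon):
    ``x = R * dlon * cos(ref_lat)``, ``y = R * dlat`` (angles in radians,
    R the mean Earth radius).  Adequate over a wind facility's < 20 km
    extent; exactly invertible by :func:`enu_unproject`.

    Accepts scalars or arrays; returns ``(x_east_m, y_north_m)``.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(lon))):
        raise ValueError("coordinates must be finite")
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("latitude must be in [-90, 90], longitude in [-180, 180]")
    x = EARTH_RADIUS_M * np.radians(lon - ref_lon) * math.cos(math.radians(ref_lat))
    y = EARTH_RADIUS_M * np.radians(lat - ref_lat)
    if x.ndim == 0:
        return float(x), float(y)
    return x, y


def enu_unproject(x, y, ref_lat: float, ref_lon: float):
    """Inverse of :func:`enu_project`; returns ``(lat, lon)`` in degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lat = ref_lat + np.degrees(y / EARTH_RADIUS_M)
    lon = ref_lon + np.degrees(
        x / (EARTH_RADIUS_M * math.cos(math.radians(ref_lat)))
    )
    if lat.ndim == 0:
        return float(lat), float(lon)
    return lat, lon


def min_blade_height(max_blade_height: float, rotor_diameter: float) -> float:
    """Lowest blade-tip height: maximum height minus twice the blade length.

    Blade length is half the rotor diameter, so the minimum is
    ``max_blade_height - rotor_diameter``.
    """
    out = max_blade_height - rotor_diameter
    if out < 0:
        raise ValueError(
            "turbine would sweep below ground: "
            f"max_blade_height {max_blade_height} < rotor_diameter {rotor_diameter}"
        )
    return out


def build_zones(
    turbine: TurbineSpec,
    criteria: CurtailmentCriteria,
    center_xy: tuple[float, float] = (0.0, 0.0),
) -> dict[str, ZoneCylinder]:
    """Build the rotor-swept, inner and outer cylinders for one turbine.

    The RSZ radius is the rotor radius plus ``criteria.rsz_buffer``; its
    altitude band runs from the minimum to the maximum blade height.  The
    curtailment cylinders are centred on the hub height and clipped at the
    ground (z = 0).
    """
    rsz = ZoneCylinder(
        center_xy=center_xy,
        radius=turbine.rotor_diameter / 2 + criteria.rsz_buffer,
        z_min=min_blade_height(turbine.max_blade_height, turbine.rotor_diameter),
        z_max=turbine.max_blade_height,
    )
    inner = ZoneCylinder(
        center_xy=center_xy,
        radius=criteria.inner_radius,
        z_min=max(0.0, turbine.hub_height - criteria.inner_height / 2),
        z_max=turbine.hub_height + criteria.inner_height / 2,
    )
    outer = ZoneCylinder(
        center_xy=center_xy,
        radius=criteria.outer_radius,
        z_min=max(0.0, turbine.hub_height - criteria.outer_height / 2),
        z_max=turbine.hub_height + criteria.outer_height / 2,
    )
    return {"rsz": rsz, "inner": inner, "outer": outer}


def point_in_cylinder(point, cyl: ZoneCylinder):
    """Closed-boundary membership test; point is ``(x, y, z)`` or ``(n, 3)``."""
    p = np.asarray(point, dtype=float)
    squeeze = p.ndim == 1
    p = np.atleast_2d(p)
    cx, cy = cyl.center_xy
    d2 = (p[:, 0] - cx) ** 2 + (p[:, 1] - cy) ** 2
    inside = (
        (d2 <= cyl.radius**2) & (p[:, 2] >= cyl.z_min) & (p[:, 2] <= cyl.z_max)
    )
    return bool(inside[0]) if squeeze else inside


def ray_cylinder_entry_time(pos, vel, cyl: ZoneCylinder):
    """First time t >= 0 at which ``pos + t*vel`` lies inside the cylinder.

    Solves the horizontal circle-crossing quadratic and intersects with
    the altitude-band interval.  Returns ``None`` when the extrapolated
    straight line never enters; 0.0 when the start point is already inside.
    """
    px, py, pz = (float(v) for v in pos)
    vx, vy, vz = (float(v) for v in vel)
    cx, cy = cyl.center_xy
    px -= cx
    py -= cy

    if vx == 0.0 and vy == 0.0 and vz == 0.0:
        return 0.0 if point_in_cylinder((px + cx, py + cy, pz), cyl) else None

    # Horizontal interval where x^2 + y^2 <= r^2.
    a = vx * vx + vy * vy
    if a == 0.0:
        if px * px + py * py > cyl.radius**2:
            return None
        h_lo, h_hi = -math.inf, math.inf
    else:
        b = 2.0 * (px * vx + py * vy)
        c = px * px + py * py - cyl.radius**2
        disc = b * b - 4.0 * a * c
        if disc < 0.0:
            return None
        sq = math.sqrt(disc)
        h_lo = (-b - sq) / (2.0 * a)
        h_hi = (-b + sq) / (2.0 * a)

    # Vertical interval where z_min <= z + t*vz <= z_max.
    if vz == 0.0:
        if not (cyl.z_min <= pz <= cyl.z_max):
            return None
        v_lo, v_hi = -math.inf, math.inf
    else:
        t1 = (cyl.z_min - pz) / vz
        t2 = (cyl.z_max - pz) / vz
        v_lo, v_hi = min(t1, t2), max(t1, t2)

    lo = max(h_lo, v_lo, 0.0)
    hi = min(h_hi, v_hi)
    if lo > hi:
        return None
    return lo
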
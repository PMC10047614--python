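"""Planar distance geometry for escape encounters.

All coordinates are planar metres (project geographic input upstream).
"""

from __future__ import annotations

import math
from typing import NamedTuple, Optional

from shapely.geometry import Polygon


class Point(NamedTuple):
    """A planar position in metres."""

    x: float
    y: float


class DegenerateGeometryError(ValueError):
    """Raised for zero-length escape segments (apply the short-flight rule first)."""


class MissingDataError(ValueError):
    """Raised when neither coordinates nor a field measurement determine a distance."""


def local_tangent_xy(lat_deg, lon_deg, lat0_deg: float, lon0_deg: float):
    """Project geographic coordinates to planar metres around a local origin.

    Equirectangular local-tangent approximation (spherical Earth, radius
    6371008.8 m), adequate for the park-scale extents this package works
    at; use a proper projected CRS for anything larger. Returns (x, y)
    east/north metres relative to (lat0, lon0). Accepts scalars or arrays.
    """
    import numpy as np
    R = 6371008.8
    lat = np.radians(np.asarray(lat_deg, dtype=float))
    lon = np.radians(np.asarray(lon_deg, dtype=float))
    lat0 = math.radians(lat0_deg)
    lon0 = math.radians(lon0_deg)
    x = R * math.cos(lat0) * (lon - lon0)
    y = R * (lat - lat0)
    return x, y


def slant_distance(horizontal_m: float, observer_eye_height_m: float,
                   perch_height_m: float) -> float:
    """Straight-line distance from observer eye to a perched bird.

    Field rangefinders return the slant distance; when only the horizontal
    distance to the perch is measurable (bird obscured), the slant distance
    is reconstructed from observer eye height and perch height.

    Parameters
    ----------
    horizontal_m : ground distance to the point under the perch, >= 0.
    observer_eye_height_m : observer eye height above ground, >= 0.
    perch_height_m : perch height above ground, >= 0 (sampling protocol
        restricts perches to <= 10 m).
    """
    if horizontal_m < 0 or observer_eye_height_m < 0 or perch_height_m < 0:
        raise ValueError("distances and heights must be non-negative")
    if perch_height_m > 10:
        raise ValueError("perch_height_m above the 10 m sampling criterion")
    return math.hypot(horizontal_m, observer_eye_height_m - perch_height_m)


def route_rectangle(initial: Point, refuge: Point, width_m: float = 10.0) -> Polygon:
    """Oriented rectangle spanning the escape route.

    The rectangle is centred on the segment initial->refuge: its length is the
    flight distance and it extends ``width_m / 2`` to either side of the
    segment. Corners are returned counter-clockwise starting at the
    initial-end, right-hand corner (right of the direction of flight).
    """
    dx = refuge.x - initial.x
    dy = refuge.y - initial.y
    length = math.hypot(dx, dy)
    if length == 0.0:
        raise DegenerateGeometryError(
            "initial and refuge coincide; short flights (<= 5 m) take "
            "route connectivity 1.0 and have no route rectangle")
    if width_m <= 0:
        raise ValueError("width_m must be positive")
    ux, uy = dx / length, dy / length          # along-route unit vector
    nx, ny = uy, -ux                           # right-hand normal
    h = width_m / 2.0
    corners = [
        (initial.x + h * nx, initial.y + h * ny),
        (refuge.x + h * nx, refuge.y + h * ny),
        (refuge.x - h * nx, refuge.y - h * ny),
        (initial.x - h * nx, initial.y - h * ny),
    ]
    return Polygon(corners)


def distance_fled(initial: Point, refuge: Optional[Point],
                  measured_m: Optional[float] = None) -> float:
    """Straight-line distance from initial position to refuge.

    For short flights the field protocol records initial and refuge as the
    same coordinate and keeps only the tape/rangefinder measurement, so
    coincident (or missing) refuge coordinates fall back to ``measured_m``.
    """
    if refuge is not None:
        d = math.hypot(refuge.x - initial.x, refuge.y - initial.y)
        if d > 0:
            return d
    if measured_m is not None:
        return float(measured_m)
    raise MissingDataError(
        "refuge coordinates coincide with the initial position and no "
        "measured distance was supplied")
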
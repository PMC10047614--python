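"""Habitat-connectivity metrics for escape encounters.

Two bespoke metrics quantify connectivity at the two stages of an escape:

* **Perch density (PD)** at the bird's initial position — an adapted
  point-centred quarter estimate: the inverse of the mean distance to the
  nearest perch in each of the four cardinal quadrants (units m^-1).
* **Route connectivity (RC)** along the escape route — the proportion of
  points of a 1 x 1 m grid, laid over a 10 m wide rectangle spanning the
  route, whose raster cell holds vegetation or perchable infrastructure.
  Flights of 5 m or less take RC = 1.0 by convention: at that range the
  bird never leaves its immediate cover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import Point, distance_fled, route_rectangle
from .raster import PerchSet, VegetationRaster

SHORT_FLIGHT_M = 5.0        # flights at or under this distance take RC = 1.0
DEFAULT_MAX_RADIUS_M = 100.0
MIN_PERCH_DISTANCE_M = 0.1  # floor for a bird sitting on a perch

#: quadrant order used throughout: NE, SE, SW, NW
QUADRANT_NAMES = ("NE", "SE", "SW", "NW")


@dataclass
class ConnectivityMetrics:
    """Per-encounter connectivity measurements and their audit trail."""

    perch_density: Optional[float] = None      # PD, m^-1
    route_connectivity: Optional[float] = None  # RC, proportion in [0, 1]
    quadrant_distances: Optional[np.ndarray] = None
    n_grid_points: int = 0
    n_vegetated_points: int = 0
    flags: list[str] = field(default_factory=list)


def _quadrant_index(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Quadrant of each offset: 0=NE, 1=SE, 2=SW, 3=NW.

    The quadrants are demarcated by the cardinal half-lines; an offset lying
    exactly on an axis belongs to the clockwise-next quadrant (N axis -> NE,
    E axis -> SE, S axis -> SW, W axis -> NW).
    """
    q = np.full(dx.shape, -1, dtype=int)
    q[(dx >= 0) & (dy > 0)] = 0
    q[(dx > 0) & (dy <= 0)] = 1
    q[(dx <= 0) & (dy < 0)] = 2
    q[(dx < 0) & (dy >= 0)] = 3
    return q


def pcq_perch_density(bird: Point, perches: PerchSet,
                      max_radius_m: float = DEFAULT_MAX_RADIUS_M,
                      classical: bool = False) -> ConnectivityMetrics:
    """Point-centred quarter perch density at the bird's initial position.

    Distance to the nearest perch is taken in each cardinal quadrant; an
    empty quadrant substitutes ``max_radius_m`` (and is flagged) rather than
    being dropped, which would bias density upward. The density is the
    literal inverse of the mean of the four distances (m^-1); with
    ``classical=True`` the classical point-centred quarter areal density
    1 / mean^2 (m^-2) is returned instead, for sensitivity analysis.
    """
    if len(perches) == 0 and not math.isfinite(max_radius_m):
        raise ValueError("no perches and infinite max_radius_m")
    dists = np.full(4, float(max_radius_m))
    flags: list[str] = []
    if len(perches) > 0:
        dx = perches.points[:, 0] - bird.x
        dy = perches.points[:, 1] - bird.y
        r = np.hypot(dx, dy)
        on_bird = r == 0.0
        if on_bird.any():
            flags.append("perch_coincident_with_bird")
            r[on_bird] = MIN_PERCH_DISTANCE_M
        q = _quadrant_index(dx, dy)
        q[on_bird] = 0  # direction undefined; floored distance, arbitrary quadrant
        for k in range(4):
            in_q = q == k
            if in_q.any():
                dists[k] = min(dists[k], float(r[in_q].min()))
            else:
                flags.append(f"empty_quadrant_{QUADRANT_NAMES[k]}")
    else:
        flags.extend(f"empty_quadrant_{n}" for n in QUADRANT_NAMES)
    floored = dists < MIN_PERCH_DISTANCE_M
    if floored.any():
        dists[floored] = MIN_PERCH_DISTANCE_M
    mean_d = dists.mean()
    density = 1.0 / mean_d ** 2 if classical else 1.0 / mean_d
    return ConnectivityMetrics(
        perch_density=float(density),
        quadrant_distances=dists,
        flags=flags,
    )


def route_connectivity(initial: Point, refuge: Optional[Point],
                       raster: VegetationRaster,
                       grid_spacing_m: float = 1.0,
                       width_m: float = 10.0,
                       measured_m: Optional[float] = None,
                       frame: str = "route") -> ConnectivityMetrics:
    """Escape-route connectivity: vegetated fraction of the route rectangle.

    With ``frame="route"`` (default) grid points are laid out in the
    rectangle's local frame — rows along the route axis, columns across it,
    the first row ``grid_spacing_m / 2`` in from the initial end — which
    makes RC invariant to where the encounter sits on the map. With
    ``frame="world"`` the points are the world-grid cell centres falling
    inside the rectangle, reproducing a GIS overlay of a fixed map grid.
    Points falling outside the raster extent count as non-vegetated and are
    flagged, keeping the denominator "all points within the escape route".
    """
    if grid_spacing_m <= 0:
        raise ValueError("grid_spacing_m must be positive")
    if frame not in ("route", "world"):
        raise ValueError(f"unknown grid frame {frame!r}")
    d = distance_fled(initial, refuge, measured_m)
    if d <= SHORT_FLIGHT_M:
        return ConnectivityMetrics(route_connectivity=1.0, n_grid_points=0,
                                   flags=["short_flight_rc_1"])
    assert refuge is not None  # a > 5 m flight has distinct coordinates
    length = math.hypot(refuge.x - initial.x, refuge.y - initial.y)
    ux, uy = (refuge.x - initial.x) / length, (refuge.y - initial.y) / length
    nx, ny = uy, -ux
    if frame == "world":
        rect = route_rectangle(initial, refuge, width_m)
        x0, y0, x1, y1 = rect.bounds
        s = grid_spacing_m
        cxs = (np.arange(math.floor(x0 / s), math.ceil(x1 / s)) + 0.5) * s
        cys = (np.arange(math.floor(y0 / s), math.ceil(y1 / s)) + 0.5) * s
        xs, ys = np.meshgrid(cxs, cys, indexing="ij")
        # inside test in the rectangle's local coordinates
        relx, rely = xs - initial.x, ys - initial.y
        u = relx * ux + rely * uy
        v = relx * nx + rely * ny
        keep = (u >= 0) & (u <= length) & (np.abs(v) <= width_m / 2.0)
        xs, ys = xs[keep], ys[keep]
    else:
        n_along = max(int(math.floor(length / grid_spacing_m)), 1)
        n_across = max(int(round(width_m / grid_spacing_m)), 1)
        u = (np.arange(n_along) + 0.5) * grid_spacing_m
        v = (np.arange(n_across) + 0.5) * grid_spacing_m - width_m / 2.0
        uu, vv = np.meshgrid(u, v, indexing="ij")
        xs = initial.x + uu * ux + vv * nx
        ys = initial.y + uu * uy + vv * ny
    flags: list[str] = []
    inside = raster.contains(xs.ravel(), ys.ravel())
    if not inside.all():
        flags.append("grid_points_outside_raster")
    veg = raster.vegetated_at(xs.ravel(), ys.ravel())
    n_total = veg.size
    if n_total == 0:
        raise ValueError("grid spacing too coarse: no grid point falls in the route")
    n_veg = int(veg.sum())
    return ConnectivityMetrics(
        route_connectivity=n_veg / n_total,
        n_grid_points=n_total,
        n_vegetated_points=n_veg,
        flags=flags,
    )


def annotate_encounters(table, raster: Optional[VegetationRaster],
                        perches: Optional[PerchSet],
                        max_radius_m: float = DEFAULT_MAX_RADIUS_M):
    """Append pd_per_m / rc_prop / rc_n_points / rc_flags columns.

    Rows without usable coordinates get NA metrics (and are flagged); they
    surface later in the exclusion cascade rather than being dropped here.
    """
    table = table.copy()
    pd_col, rc_col, n_col, flag_col = [], [], [], []
    for row in table.itertuples(index=False):
        flags = []
        if perches is not None and np.isfinite(row.x0) and np.isfinite(row.y0):
            m = pcq_perch_density(Point(row.x0, row.y0), perches, max_radius_m)
            pd_col.append(m.perch_density)
            flags.extend(m.flags)
        else:
            pd_col.append(np.nan)
            flags.append("pd_unavailable")
        refuge_known = np.isfinite(row.x1) and np.isfinite(row.y1)
        measured = row.distance_fled_m if np.isfinite(row.distance_fled_m) else None
        if raster is not None and np.isfinite(row.x0) and np.isfinite(row.y0) \
                and (refuge_known or measured is not None):
            refuge = Point(row.x1, row.y1) if refuge_known else None
            m = route_connectivity(Point(row.x0, row.y0), refuge, raster,
                                   measured_m=measured)
            rc_col.append(m.route_connectivity)
            n_col.append(m.n_grid_points)
            flags.extend(m.flags)
        else:
            rc_col.append(np.nan)
            n_col.append(0)
            flags.append("rc_unavailable")
        flag_col.append(";".join(flags))
    table["pd_per_m"] = pd_col
    table["rc_prop"] = rc_col
    table["rc_n_points"] = n_col
    table["rc_flags"] = flag_col
    return table
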
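"""Vegetation rasters and perch point layers.

The vegetation layer is a boolean cover grid at (by default) 1 m resolution:
True marks cells with shrubs, trees or perchable infrastructure. Grids are
stored on disk as ESRI ASCII rasters (plain text); perch layers as GeoJSON
point FeatureCollections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .geometry import Point


@dataclass
class VegetationRaster:
    """Boolean cover grid anchored at ``origin`` (lower-left corner).

    ``cells[iy, ix]`` covers the square
    ``[origin.x + ix*cell_size, origin.x + (ix+1)*cell_size) x
    [origin.y + iy*cell_size, origin.y + (iy+1)*cell_size)``;
    row 0 is the southernmost row.
    """

    origin: Point
    cell_size: float
    cells: np.ndarray  # bool, shape (nrows, ncols)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.cells = np.asarray(self.cells, dtype=bool)
        if self.cells.ndim != 2:
            raise ValueError("cells must be a 2-D grid")

    @property
    def width_m(self) -> float:
        return self.cells.shape[1] * self.cell_size

    @property
    def height_m(self) -> float:
        return self.cells.shape[0] * self.cell_size

    def cover_fraction(self) -> float:
        return float(self.cells.mean())

    def contains(self, x, y):
        """Vectorised point-in-extent test."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return ((x >= self.origin.x) & (x < self.origin.x + self.width_m)
                & (y >= self.origin.y) & (y < self.origin.y + self.height_m))

    def vegetated_at(self, x, y):
        """Cover value of the cell containing each point; False outside the extent."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = self.contains(x, y)
        ix = np.floor((x - self.origin.x) / self.cell_size).astype(int)
        iy = np.floor((y - self.origin.y) / self.cell_size).astype(int)
        out = np.zeros(np.broadcast(x, y).shape, dtype=bool)
        if out.ndim == 0:
            return bool(inside) and bool(self.cells[int(iy), int(ix)])
        out[inside] = self.cells[iy[inside], ix[inside]]
        return out


def write_ascii_grid(raster: VegetationRaster, path: str | Path) -> None:
    """Write the cover grid as an ESRI ASCII raster (1 = cover, 0 = open)."""
    nrows, ncols = raster.cells.shape
    header = (f"ncols {ncols}\nnrows {nrows}\n"
              f"xllcorner {raster.origin.x}\nyllcorner {raster.origin.y}\n"
              f"cellsize {raster.cell_size}\nNODATA_value -9999\n")
    body = np.flipud(raster.cells.astype(np.int8))  # ASCII grids run north to south
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%d")


def read_ascii_grid(path: str | Path) -> VegetationRaster:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    cells = np.flipud(np.atleast_2d(data) > 0)
    if cells.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid body does not match its header dimensions")
    return VegetationRaster(
        origin=Point(header["xllcorner"], header["yllcorner"]),
        cell_size=header["cellsize"],
        cells=cells,
    )


@dataclass
class PerchSet:
    """Candidate perches: any solid surface able to support a bird
    (trees, shrubs, fences, buildings, powerlines)."""

    points: np.ndarray  # float, shape (n, 2)
    labels: Optional[Sequence[str]] = field(default=None)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("perch coordinates must be finite")
        if self.labels is not None and len(self.labels) != len(self.points):
            raise ValueError("labels length must match points")

    def __len__(self) -> int:
        return len(self.points)


def write_perches_geojson(perches: PerchSet, path: str | Path) -> None:
    features = []
    for i, (x, y) in enumerate(perches.points):
        props = {}
        if perches.labels is not None:
            props["kind"] = perches.labels[i]
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            "properties": props,
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def read_perches_geojson(path: str | Path) -> PerchSet:
    with open(path) as fh:
        fc = json.load(fh)
    pts, labels, any_label = [], [], False
    for feat in fc.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Point":
            raise ValueError("perch layer must contain Point features only")
        pts.append(geom["coordinates"][:2])
        kind = feat.get("properties", {}).get("kind")
        labels.append(kind)
        any_label = any_label or kind is not None
    return PerchSet(points=np.asarray(pts, dtype=float).reshape(-1, 2),
                    labels=labels if any_label else None)
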
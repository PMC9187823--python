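"""Lightweight geospatial I/O: grids, ASCII rasters, GeoJSON, run manifests.

All formats are plain text so that runs are diffable and portable: rasters
are stored as ESRI ASCII grids, vector layers as GeoJSON, attributes as CSV.
Coordinates are always in a metric (projected) CRS; the CRS is carried as an
opaque identifier string and never reprojected.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import mapping, shape

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Regular north-up raster grid in metric coordinates.

    ``x0, y0`` is the lower-left corner; row 0 of an associated value array
    is the *northernmost* row (ESRI ASCII convention).
    """

    x0: float
    y0: float
    cell: float
    ncols: int
    nrows: int

    def __post_init__(self) -> None:
        if self.cell <= 0 or self.ncols < 1 or self.nrows < 1:
            raise ValueError("grid must have positive cell size and shape")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.x0,
            self.y0,
            self.x0 + self.ncols * self.cell,
            self.y0 + self.nrows * self.cell,
        )

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of cell-centre coordinates, shape (nrows, ncols)."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell
        ys = self.y0 + (np.arange(self.nrows) + 0.5) * self.cell
        # row 0 is the top (max y)
        ys = ys[::-1]
        return np.meshgrid(xs, ys)

    @classmethod
    def from_bounds(cls, bounds, cell: float) -> "GridSpec":
        x0, y0, x1, y1 = bounds
        if x1 <= x0 or y1 <= y0:
            raise ValueError("degenerate bounds")
        ncols = int(np.ceil((x1 - x0) / cell))
        nrows = int(np.ceil((y1 - y0) / cell))
        return cls(x0=float(x0), y0=float(y0), cell=float(cell), ncols=ncols, nrows=nrows)


@dataclass
class Raster:
    """A single-band raster: value grid + placement. ``nan`` marks nodata in memory."""

    grid: GridSpec
    values: np.ndarray
    crs: str = "local-metric"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"value array shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def cell(self) -> float:
        return self.grid.cell

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


def write_asc(raster: Raster, path: str | Path, fmt: str = "%.6g") -> None:
    """Write a raster as an ESRI ASCII grid (nodata encoded as -9999)."""
    g = raster.grid
    vals = np.where(np.isfinite(raster.values), raster.values, NODATA)
    header = (
        f"ncols {g.ncols}\n"
        f"nrows {g.nrows}\n"
        f"xllcorner {g.x0!r}\n"
        f"yllcorner {g.y0!r}\n"
        f"cellsize {g.cell!r}\n"
        f"NODATA_value {NODATA:g}\n"
    )
    path = Path(path)
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=fmt)


def read_asc(path: str | Path, crs: str = "local-metric") -> Raster:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)
    nodata = header.get("nodata_value", NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    grid = GridSpec(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cell=header["cellsize"],
        ncols=int(header["ncols"]),
        nrows=int(header["nrows"]),
    )
    return Raster(grid=grid, values=vals, crs=crs)


def write_geojson(path: str | Path, geometries, properties=None, crs: str = "local-metric") -> None:
    """Write geometries (+ parallel property dicts) as a GeoJSON FeatureCollection."""
    geometries = list(geometries)
    if properties is None:
        properties = [{} for _ in geometries]
    features = [
        {"type": "Feature", "geometry": mapping(geom), "properties": props}
        for geom, props in zip(geometries, properties, strict=True)
    ]
    doc = {"type": "FeatureCollection", "crs_id": crs, "features": features}
    Path(path).write_text(json.dumps(doc))


def read_geojson(path: str | Path):
    """Read a GeoJSON FeatureCollection -> (list of shapely geoms, list of property dicts)."""
    doc = json.loads(Path(path).read_text())
    geoms = [shape(f["geometry"]) for f in doc["features"]]
    props = [f.get("properties", {}) for f in doc["features"]]
    return geoms, props


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class Manifest:
    """Checksummed record of the files a pipeline stage wrote."""

    stage: str
    config_echo: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)

    def add(self, path: str | Path) -> None:
        path = Path(path)
        self.files[path.name] = file_sha256(path)

    def write(self, path: str | Path) -> None:
        doc = {"stage": self.stage, "config": self.config_echo, "files": self.files}
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True, default=str))
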
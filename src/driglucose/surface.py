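"""Risk mapping: score the index on a residential 50-m grid.

Every unmasked grid cell is treated as the residence of a standard
pedestrian (fixed 4.7 km/h walking speed, 20-min maximum): ring zones are
computed from the cell centre, collapsed to an exposure profile with the
same distance-decay weights as for participants, and scored with a fitted
(or published + calibrated) index model. Non-residential and unsnappable
cells become nodata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from .exposure import CensusAreaSet, exposure_profile
from .index import IndexModelResults
from .io_utils import GridSpec, Raster
from .network import (
    STANDARD_SPEED_KMH,
    SnapError,
    StreetNetwork,
    WalkProfile,
    compute_ring_set,
    snap_origin,
)


def residential_mask(landuse_polygons, residential_flags, grid: GridSpec) -> np.ndarray:
    """Boolean grid: True where the cell centre lies in a residential polygon."""
    flags = list(residential_flags)
    polys = list(landuse_polygons)
    if len(polys) != len(flags):
        raise ValueError("polygon count != flag count")
    mask = np.zeros(grid.shape, dtype=bool)
    res_polys = [p for p, f in zip(polys, flags) if f]
    if not res_polys:
        return mask
    X, Y = grid.cell_centres()
    xs, ys = X.ravel(), Y.ravel()
    flat = mask.ravel()
    for poly in res_polys:
        minx, miny, maxx, maxy = poly.bounds
        cand = np.flatnonzero((xs >= minx) & (xs <= maxx) & (ys >= miny) & (ys <= maxy) & ~flat)
        if cand.size:
            inside = shapely.contains_xy(poly, xs[cand], ys[cand])
            flat[cand[inside]] = True
    return flat.reshape(grid.shape)


@dataclass
class RiskSurface:
    """Scored index raster plus provenance and run counters."""

    raster: Raster
    model_source: str
    speed_kmh: float
    logit_b: float
    logit_m: float | None
    n_scored: int = 0
    n_masked: int = 0
    n_unsnappable: int = 0
    report: dict = field(default_factory=dict)

    def run_report(self) -> dict:
        return {
            "model": self.model_source,
            "speed_kmh": self.speed_kmh,
            "logit_b": self.logit_b,
            "logit_m": self.logit_m,
            "cells_scored": self.n_scored,
            "cells_masked": self.n_masked,
            "cells_unsnappable": self.n_unsnappable,
            **self.report,
        }


def map_index(
    grid: GridSpec,
    network: StreetNetwork,
    areas: CensusAreaSet,
    ndvi: Raster,
    model: IndexModelResults,
    speed_kmh: float = STANDARD_SPEED_KMH,
    mask: np.ndarray | None = None,
    increment_min: float = 2.0,
    max_time_min: float = 20.0,
    buffer_m: float = 40.0,
    max_snap_m: float = 500.0,
    logit_b: float = 0.005,
    logit_m: float | None = None,
) -> RiskSurface:
    """Score every unmasked grid cell; returns the index surface in [-1, 1].

    Ring sets are memoized by snapped network position (edge + offset
    rounded to the millimetre), so stacked cells snapping to one point are
    computed once.
    """
    if mask is not None and mask.shape != grid.shape:
        raise ValueError("mask shape != grid shape")
    values = np.full(grid.shape, np.nan)
    X, Y = grid.cell_centres()
    cache: dict = {}
    n_scored = n_masked = n_unsnap = 0
    profile = WalkProfile(speed_kmh=speed_kmh)
    for r in range(grid.nrows):
        for c in range(grid.ncols):
            if mask is not None and not mask[r, c]:
                n_masked += 1
                continue
            x, y = float(X[r, c]), float(Y[r, c])
            try:
                snapped = snap_origin(network, (x, y), max_snap_m=max_snap_m)
            except SnapError:
                n_unsnap += 1
                continue
            key = (snapped.edge, round(snapped.offset_m, 3))
            if key not in cache:
                rings = compute_ring_set(
                    network,
                    snapped.point,
                    profile,
                    increment_min=increment_min,
                    max_time_min=max_time_min,
                    buffer_m=buffer_m,
                    max_snap_m=max_snap_m,
                )
                prof = exposure_profile(
                    rings, areas, ndvi, steepness_b=logit_b, midpoint_m=logit_m
                )
                frame = prof.values.to_frame().T
                if frame.isna().any().any():
                    cache[key] = np.nan
                else:
                    cache[key] = float(model.score(frame)[0])
            val = cache[key]
            if np.isnan(val):
                n_unsnap += 1
            else:
                values[r, c] = val
                n_scored += 1
    return RiskSurface(
        raster=Raster(grid=grid, values=values, crs=areas.crs),
        model_source=model.source,
        speed_kmh=speed_kmh,
        logit_b=logit_b,
        logit_m=logit_m,
        n_scored=n_scored,
        n_masked=n_masked,
        n_unsnappable=n_unsnap,
    )
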
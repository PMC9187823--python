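"""Exposure assessment: ring-zone overlays with distance-decay weighting.

For one location the engine overlays its ten walk-time rings on (a) census
polygons carrying area-level socioeconomic (SES) attributes and (b) an NDVI
greenspace raster, computes per-ring statistics, and collapses the ten rings
into a single exposure value per variable using logit-shaped distance-decay
weights. The result is one 15-value exposure profile: 11 SES variables plus
4 NDVI metrics (median, standard deviation, 95th and 5th percentiles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.strtree import STRtree

from .io_utils import Raster, read_geojson, write_geojson
from .network import IsochroneRingSet

#: The 11 area-level census SES variables (percentages unless noted; incomes
#: in thousands of CAD).
SES_VARIABLES: tuple[str, ...] = (
    "income_individual_mean",
    "income_household_median",
    "low_income_prevalence",
    "commute_active_pct",
    "labour_participation_pct",
    "transfer_payments_pct",
    "unemployment_pct",
    "lone_parent_pct",
    "no_degree_pct",
    "dwellings_owned_pct",
    "dwellings_rented_pct",
)

#: The 4 NDVI greenspace metrics computed per ring then distance-weighted.
NDVI_METRICS: tuple[str, ...] = ("ndvi_median", "ndvi_sd", "ndvi_p95", "ndvi_p5")

ALL_VARIABLES: tuple[str, ...] = SES_VARIABLES + NDVI_METRICS


class AlignmentError(ValueError):
    """Raster grids do not share one placement."""


@dataclass
class CensusAreaSet:
    """Census polygons tiling the study area with an SES attribute table."""

    polygons: list
    table: pd.DataFrame
    crs: str = "local-metric"
    _tree: STRtree | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.polygons) != len(self.table):
            raise ValueError("polygon count != attribute row count")

    def tree(self) -> STRtree:
        if self._tree is None:
            self._tree = STRtree(self.polygons)
        return self._tree

    def area_index_at(self, x: float, y: float) -> int | None:
        """Index of the polygon containing (x, y), or None."""
        pt = shapely.points(x, y)
        for idx in self.tree().query(pt, predicate="intersects"):
            return int(idx)
        return None

    def write(self, geo_path: str | Path, csv_path: str | Path) -> None:
        props = [{"area_id": int(i)} for i in range(len(self.polygons))]
        write_geojson(geo_path, self.polygons, props, crs=self.crs)
        self.table.to_csv(csv_path, index=False)

    @classmethod
    def read(cls, geo_path: str | Path, csv_path: str | Path) -> "CensusAreaSet":
        geoms, _ = read_geojson(geo_path)
        return cls(polygons=geoms, table=pd.read_csv(csv_path))


def compute_ndvi(red: Raster, nir: Raster) -> Raster:
    """Normalized Difference Vegetation Index, (NIR - Red) / (NIR + Red).

    Cells where the denominator vanishes (or either band is nodata) become
    nodata rather than propagating infinities.
    """
    if red.grid != nir.grid:
        raise AlignmentError("red and NIR band grids are not aligned")
    total = nir.values + red.values
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = (nir.values - red.values) / total
    ndvi = np.where(total == 0, np.nan, ndvi)
    return Raster(grid=red.grid, values=ndvi, crs=red.crs)


def ring_ses_means(
    rings: IsochroneRingSet, areas: CensusAreaSet, variables=SES_VARIABLES
) -> pd.DataFrame:
    """Area-weighted mean of each SES variable over the polygons each ring cuts.

    Entry (k, j) averages variable j over the census polygons intersecting
    ring k, weighted by intersection area — the homogeneity assumption:
    a polygon's attribute applies uniformly across its extent. Rings with no
    census coverage yield NaN and a coverage warning; the distance weights
    are renormalized over available rings downstream.
    """
    missing = [v for v in variables if v not in areas.table.columns]
    if missing:
        raise KeyError(f"variables absent from census table: {missing}")
    tree = areas.tree()
    out = np.full((rings.n_rings, len(variables)), np.nan)
    values = areas.table[list(variables)].to_numpy(dtype=float)
    for k, ring in enumerate(rings.rings):
        if ring.is_empty:
            continue
        idxs = tree.query(ring, predicate="intersects")
        weights, rows = [], []
        for i in idxs:
            inter = ring.intersection(areas.polygons[int(i)])
            if inter.area > 0:
                weights.append(inter.area)
                rows.append(int(i))
        if not rows:
            warnings.warn(f"ring {k + 1} has no census coverage", stacklevel=2)
            continue
        w = np.asarray(weights)
        out[k] = (values[rows] * w[:, None]).sum(axis=0) / w.sum()
    return pd.DataFrame(out, columns=list(variables), index=np.arange(1, rings.n_rings + 1))


def ring_ndvi_stats(rings: IsochroneRingSet, ndvi: Raster) -> pd.DataFrame:
    """Per-ring NDVI summaries: median, sample SD, 95th and 5th percentiles.

    A raster cell belongs to the ring containing its centre. Percentiles use
    the linear-interpolation definition; the SD is the sample (n-1) SD, 0.0
    for a single cell. Rings without any valid cell yield NaN + warning.
    """
    X, Y = ndvi.grid.cell_centres()
    xs, ys, vals = X.ravel(), Y.ravel(), ndvi.values.ravel()
    valid = np.isfinite(vals)
    out = np.full((rings.n_rings, 4), np.nan)
    for k, ring in enumerate(rings.rings):
        if ring.is_empty:
            warnings.warn(f"ring {k + 1} contains no valid NDVI cells", stacklevel=2)
            continue
        minx, miny, maxx, maxy = ring.bounds
        cand = valid & (xs >= minx) & (xs <= maxx) & (ys >= miny) & (ys <= maxy)
        if cand.any():
            inside = shapely.contains_xy(ring, xs[cand], ys[cand])
        else:
            inside = np.zeros(0, dtype=bool)
        v = vals[cand][inside] if inside.size else np.empty(0)
        if v.size == 0:
            warnings.warn(f"ring {k + 1} contains no valid NDVI cells", stacklevel=2)
            continue
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        out[k] = [np.median(v), sd, np.percentile(v, 95), np.percentile(v, 5)]
    return pd.DataFrame(out, columns=list(NDVI_METRICS), index=np.arange(1, rings.n_rings + 1))


def logit_weights(
    ring_mean_distances, steepness_b: float = 0.005, midpoint_m: float | None = None
) -> np.ndarray:
    """Distance-decay weights from a logistic function of ring mean distance.

    Raw weight ``w_k = 1 / (1 + exp(b * (d_k - m)))`` — unit weight at the
    home, half weight at the midpoint ``m`` — then normalized to sum one.
    ``b`` is per metre; ``m`` defaults to half the outermost ring's mean
    distance. ``b = 0`` gives flat (uniform) weights.
    """
    d = np.asarray(ring_mean_distances, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("ring distances must be a non-empty 1-D sequence")
    if d.size > 1 and not np.all(np.diff(d) > 0):
        raise ValueError("ring mean distances must be strictly increasing")
    if steepness_b < 0:
        raise ValueError("steepness must be non-negative")
    if midpoint_m is None:
        midpoint_m = float(d[-1]) / 2.0
    raw = 1.0 / (1.0 + np.exp(steepness_b * (d - midpoint_m)))
    return raw / raw.sum()


@dataclass
class ExposureProfile:
    """Distance-weighted exposure values for one location (11 SES + 4 NDVI)."""

    location_id: object
    values: pd.Series
    weights: np.ndarray
    missing: tuple = ()
    flags: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {"location_id": self.location_id, **self.values.to_dict()}
        row.update({f"weight_{k + 1}": w for k, w in enumerate(self.weights)})
        row["missing"] = ";".join(self.missing)
        return row


def weighted_profile(
    ring_matrix: pd.DataFrame,
    ring_stats: pd.DataFrame,
    weights: np.ndarray,
    location_id: object = None,
) -> ExposureProfile:
    """Collapse per-ring values to one exposure value per variable.

    Each output is ``sum_k w'_k * value_k`` with the weights renormalized
    over that variable's non-missing rings. A variable missing in every ring
    stays NaN and is flagged rather than silently imputed.
    """
    joined = pd.concat([ring_matrix, ring_stats], axis=1)
    w = np.asarray(weights, dtype=float)
    if len(w) != len(joined):
        raise ValueError("weight count != ring count")
    if not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ValueError("weights must sum to 1")
    out, missing = {}, []
    for col in joined.columns:
        v = joined[col].to_numpy(dtype=float)
        ok = np.isfinite(v)
        if not ok.any():
            out[col] = np.nan
            missing.append(col)
            continue
        wk = w[ok] / w[ok].sum()
        out[col] = float(v[ok] @ wk)
    return ExposureProfile(
        location_id=location_id,
        values=pd.Series(out),
        weights=w,
        missing=tuple(missing),
    )


def exposure_profile(
    rings: IsochroneRingSet,
    areas: CensusAreaSet,
    ndvi: Raster,
    steepness_b: float = 0.005,
    midpoint_m: float | None = None,
    location_id: object = None,
) -> ExposureProfile:
    """One-call overlay: ring SES means + ring NDVI stats -> weighted profile."""
    ses = ring_ses_means(rings, areas)
    stats = ring_ndvi_stats(rings, ndvi)
    w = logit_weights(rings.ring_mean_distance, steepness_b, midpoint_m)
    return weighted_profile(ses, stats, w, location_id=location_id)


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Stack ExposureProfiles into one row-per-location DataFrame."""
    return pd.DataFrame([p.as_row() for p in profiles]).set_index("location_id")
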
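"""Synthetic study areas: street networks, census SES polygons, NDVI, cohorts.

No deposited cohort exists for this method, so every downstream stage is
exercised on generated data that emulates the study setting: a connected
walkable street network, census-like polygons carrying spatially
autocorrelated socioeconomic (SES) attributes, a smooth 30-m NDVI field
optionally anti-correlated with deprivation, and a participant cohort whose
binary diabetes outcome follows a logistic model on the true local
deprivation exposure plus individual covariates at ~10% prevalence.

The generating truth (the latent deprivation field and each participant's
``true_index``) is recorded so that recovery tests can close the loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from scipy.spatial import Voronoi
from scipy.special import expit, logit
from shapely.geometry import Polygon, box

from .exposure import ALL_VARIABLES, CensusAreaSet
from .io_utils import GridSpec, Raster, write_asc
from .network import StreetNetwork

# Marginal mean, SD and signed loading on the latent deprivation field for
# each generated SES variable. Means/SDs loosely match the study cohort's
# neighbourhood characteristics; loadings echo the documented correlation
# structure of deprivation indices (income down, transfer payments up, ...).
# dwellings_rented_pct is derived as 100 - owned.
SES_GENERATOR: dict[str, tuple[float, float, float]] = {
    "income_individual_mean": (37.5, 13.8, -0.55),
    "income_household_median": (65.0, 21.4, -0.70),
    "low_income_prevalence": (9.6, 7.0, 0.65),
    "commute_active_pct": (7.4, 6.8, 0.20),
    "labour_participation_pct": (66.5, 7.7, -0.30),
    "transfer_payments_pct": (10.1, 5.4, 0.75),
    "unemployment_pct": (5.6, 2.6, 0.65),
    "lone_parent_pct": (15.0, 6.6, 0.70),
    "no_degree_pct": (20.0, 9.4, 0.60),
    "dwellings_owned_pct": (73.8, 17.7, -0.50),
}

PERCENT_VARIABLES = {name for name in SES_GENERATOR if name.endswith(("_pct", "_prevalence"))}

NDVI_BASE_MEAN = 0.34   # cohort-wide median-NDVI level
NDVI_BASE_SD = 0.09

# Log-odds per unit of each (centred) covariate in the outcome model;
# directions follow the study's bivariate associations.
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "age_z": 0.45,
    "female": -0.40,
    "bmi_z": 0.55,
    "income_cat": -0.15,
    "urban": -0.10,
    "ahei_z": -0.05,
    "met_high": -0.30,
    "smoker": 0.40,
    "drinker": -0.20,
}

# Household income categories 1..6 (<20k ... >90k) with cohort-like shares.
INCOME_CAT_PROBS = (0.045, 0.073, 0.129, 0.165, 0.213, 0.375)

_MIN_AREA_M2 = 1.0e4  # one census area needs at least ~1 ha to be meaningful


class InvalidConfigError(ValueError):
    pass


class CalibrationError(RuntimeError):
    """Target prevalence unreachable for the given effects."""


@dataclass
class ScenarioConfig:
    """All knobs of one synthetic study area; same config + seed => same bytes."""

    extent: tuple[float, float, float, float] = (0.0, 0.0, 5000.0, 5000.0)
    street_spacing: float = 150.0
    street_irregularity: float = 0.3
    n_census_areas: int = 120
    ses_spatial_range: float = 800.0
    ndvi_smoothness: float = 300.0
    ndvi_ses_coupling: float = -0.4
    ndvi_cell: float = 30.0
    n_participants: int = 5125
    true_index_log_or: float = 0.5
    covariate_effects: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    target_prevalence: float = 0.099
    seed: int = 0

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.extent
        if x1 <= x0 or y1 <= y0:
            raise InvalidConfigError("extent must have positive area")
        if self.street_spacing <= 0:
            raise InvalidConfigError("street_spacing must be positive")
        if not 0 <= self.street_irregularity <= 1:
            raise InvalidConfigError("street_irregularity must be in [0, 1]")
        if self.n_census_areas < 4:
            raise InvalidConfigError("need at least 4 census areas")
        if not 0 < self.target_prevalence < 1:
            raise InvalidConfigError("target_prevalence must be in (0, 1)")
        if not -1 <= self.ndvi_ses_coupling <= 1:
            raise InvalidConfigError("ndvi_ses_coupling must be in [-1, 1]")
        if self.seed < 0:
            raise InvalidConfigError("seed must be non-negative")

    @property
    def extent_area(self) -> float:
        x0, y0, x1, y1 = self.extent
        return (x1 - x0) * (y1 - y0)

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-specific generator derived deterministically from the seed."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stage]))


def gen_street_network(config: ScenarioConfig) -> StreetNetwork:
    """Perturbed-lattice walkable network.

    A regular grid at ``street_spacing`` is jittered by
    ``irregularity * spacing`` and thinned by random edge deletions that
    never disconnect the graph, so irregularity 0 reproduces the exact
    lattice and any setting stays fully connected.
    """
    rng = config.rng(1)
    x0, y0, x1, y1 = config.extent
    s = config.street_spacing
    nx_nodes = int(math.floor((x1 - x0) / s + 1e-9)) + 1
    ny_nodes = int(math.floor((y1 - y0) / s + 1e-9)) + 1
    if nx_nodes < 2 or ny_nodes < 2:
        raise InvalidConfigError("extent too small for the street spacing")

    jitter = config.street_irregularity * s
    coords: dict[int, tuple[float, float]] = {}
    for j in range(ny_nodes):
        for i in range(nx_nodes):
            dx, dy = rng.uniform(-0.5, 0.5, size=2) * jitter
            x = float(np.clip(x0 + i * s + dx, x0, x1))
            y = float(np.clip(y0 + j * s + dy, y0, y1))
            coords[j * nx_nodes + i] = (x, y)

    edges = []
    for j in range(ny_nodes):
        for i in range(nx_nodes):
            n = j * nx_nodes + i
            if i + 1 < nx_nodes:
                edges.append((n, n + 1))
            if j + 1 < ny_nodes:
                edges.append((n, n + nx_nodes))

    g = nx.Graph()
    for node, (x, y) in coords.items():
        g.add_node(node, pos=(x, y))
    for u, v in edges:
        (ax, ay), (bx, by) = coords[u], coords[v]
        g.add_edge(u, v, length=float(np.hypot(bx - ax, by - ay)))

    n_delete = int(round(0.25 * config.street_irregularity * g.number_of_edges()))
    if n_delete:
        candidates = list(g.edges())
        rng.shuffle(candidates)
        removed = 0
        for u, v in candidates:
            if removed >= n_delete:
                break
            data = g.edges[u, v]
            g.remove_edge(u, v)
            if nx.has_path(g, u, v):
                removed += 1
            else:
                g.add_edge(u, v, **data)
    return StreetNetwork(g)


def _bounded_voronoi(points: np.ndarray, extent) -> list[Polygon]:
    """Voronoi cells of ``points`` clipped to the extent rectangle.

    Bounding is achieved by mirroring the seed points across all four extent
    edges, which forces every original cell to be finite inside the box.
    """
    x0, y0, x1, y1 = extent
    mirrors = [
        points * (-1, 1) + (2 * x0, 0),
        points * (-1, 1) + (2 * x1, 0),
        points * (1, -1) + (0, 2 * y0),
        points * (1, -1) + (0, 2 * y1),
    ]
    vor = Voronoi(np.vstack([points, *mirrors]))
    bbox = box(x0, y0, x1, y1)
    polys = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region]).intersection(bbox)
        polys.append(poly)
    return polys


def _latent_field(centroids: np.ndarray, spatial_range: float, rng) -> np.ndarray:
    """Gaussian random field with exponential covariance at given points."""
    n = len(centroids)
    if spatial_range <= 1e-9:
        return rng.standard_normal(n)
    d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=-1)
    cov = np.exp(-d / spatial_range) + 1e-8 * np.eye(n)
    return np.linalg.cholesky(cov) @ rng.standard_normal(n)


def gen_census_areas(config: ScenarioConfig) -> CensusAreaSet:
    """Voronoi census polygons with correlated SES attributes.

    All deprivation-oriented variables share one latent Gaussian field
    (exponential covariance, range ``ses_spatial_range``) plus independent
    noise; the latent value is kept in the ``latent_deprivation`` column as
    synthetic truth. Percentages are clipped to [0, 100] and
    owned% + rented% = 100 by construction.
    """
    if config.extent_area / config.n_census_areas < _MIN_AREA_M2:
        raise InvalidConfigError(
            f"{config.n_census_areas} census areas need at least "
            f"{config.n_census_areas * _MIN_AREA_M2:.0f} m^2 of extent"
        )
    rng = config.rng(2)
    x0, y0, x1, y1 = config.extent
    pts = np.column_stack(
        [rng.uniform(x0, x1, config.n_census_areas), rng.uniform(y0, y1, config.n_census_areas)]
    )
    polys = _bounded_voronoi(pts, config.extent)
    centroids = np.array([[p.centroid.x, p.centroid.y] for p in polys])
    latent = _latent_field(centroids, config.ses_spatial_range, rng)
    latent = (latent - latent.mean()) / max(latent.std(), 1e-12)

    table: dict[str, np.ndarray] = {}
    for name, (mean, sd, loading) in SES_GENERATOR.items():
        noise = rng.standard_normal(config.n_census_areas)
        vals = mean + sd * (loading * latent + math.sqrt(1.0 - loading**2) * noise)
        if name in PERCENT_VARIABLES or name == "dwellings_owned_pct":
            vals = np.clip(vals, 0.0, 100.0)
        else:
            vals = np.clip(vals, 1.0, None)
        table[name] = vals
    table["dwellings_rented_pct"] = 100.0 - table["dwellings_owned_pct"]
    df = pd.DataFrame(table)
    df["latent_deprivation"] = latent
    df["area_id"] = np.arange(config.n_census_areas)
    return CensusAreaSet(polygons=polys, table=df)


def gen_ndvi_raster(config: ScenarioConfig, areas: CensusAreaSet) -> Raster:
    """30-m NDVI field: smooth greenness coupled to local deprivation.

    NDVI = base + sd * (c * deprivation + sqrt(1 - c^2) * smooth noise)
    where c = ``ndvi_ses_coupling`` and the smooth component is white noise
    filtered with a Gaussian kernel of scale ``ndvi_smoothness``. Infinite
    smoothness degenerates to a constant raster. Values are clipped to
    [-1, 1].
    """
    rng = config.rng(3)
    grid = GridSpec.from_bounds(config.extent, config.ndvi_cell)
    if math.isinf(config.ndvi_smoothness):
        return Raster(grid=grid, values=np.full(grid.shape, NDVI_BASE_MEAN))

    X, Y = grid.cell_centres()
    latent = areas.table["latent_deprivation"].to_numpy()
    dep = np.full(grid.shape, np.nan)
    xs, ys = X.ravel(), Y.ravel()
    flat = dep.ravel()
    for i, poly in enumerate(areas.polygons):
        minx, miny, maxx, maxy = poly.bounds
        cand = np.flatnonzero(
            (xs >= minx) & (xs <= maxx) & (ys >= miny) & (ys <= maxy) & ~np.isfinite(flat)
        )
        if cand.size:
            inside = shapely.contains_xy(poly, xs[cand], ys[cand])
            flat[cand[inside]] = latent[i]
    dep = flat.reshape(grid.shape)
    dep = np.where(np.isfinite(dep), dep, np.nanmean(dep) if np.isfinite(dep).any() else 0.0)
    dep_sd = dep.std()
    dep = (dep - dep.mean()) / dep_sd if dep_sd > 1e-12 else np.zeros_like(dep)

    sigma_cells = config.ndvi_smoothness / config.ndvi_cell
    g = gaussian_filter(rng.standard_normal(grid.shape), sigma=sigma_cells, mode="reflect")
    g_sd = g.std()
    g = (g - g.mean()) / g_sd if g_sd > 1e-12 else np.zeros_like(g)

    c = config.ndvi_ses_coupling
    fieldv = c * dep + math.sqrt(1.0 - c**2) * g
    ndvi = np.clip(NDVI_BASE_MEAN + NDVI_BASE_SD * fieldv, -1.0, 1.0)
    return Raster(grid=grid, values=ndvi)


def _calibrate_intercept(linear: np.ndarray, target: float) -> float:
    """Bisection on the intercept so that mean simulated probability hits target."""
    lo, hi = -30.0, 30.0
    f = lambda a: float(np.mean(expit(a + linear))) - target
    if f(lo) > 0 or f(hi) < 0:
        raise CalibrationError(
            f"target prevalence {target} unreachable for the given effects"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gen_cohort(
    config: ScenarioConfig,
    network: StreetNetwork,
    areas: CensusAreaSet,
    ndvi: Raster | None = None,
) -> pd.DataFrame:
    """Participant table with residences near the network and a logistic outcome.

    The outcome follows ``logit(p) = alpha + beta * true_index + sum(gamma_j
    * covariate_j)`` where ``true_index`` is the z-scored latent deprivation
    of the participant's census area, ``beta = true_index_log_or`` and the
    intercept is calibrated by bisection to the target prevalence. The
    diabetes-status *inputs* (self-report, medication, fasting glucose) are
    generated consistently with the drawn outcome so the classification rule
    reproduces it exactly.
    """
    rng = config.rng(4)
    n = config.n_participants
    x0, y0, x1, y1 = config.extent

    edges = list(network.graph.edges(data="length"))
    lengths = np.array([length for _, _, length in edges])
    pick = rng.choice(len(edges), size=n, p=lengths / lengths.sum())
    ts = rng.uniform(0, 1, n)
    offsets = rng.uniform(5.0, 25.0, n)
    sides = rng.choice([-1.0, 1.0], n)
    pos = network.positions
    xs = np.empty(n)
    ys = np.empty(n)
    for i, (e, t, off, side) in enumerate(zip(pick, ts, offsets, sides)):
        u, v, length = edges[e]
        (ax, ay), (bx, by) = pos[u], pos[v]
        px, py = ax + t * (bx - ax), ay + t * (by - ay)
        nxv, nyv = -(by - ay), (bx - ax)
        norm = math.hypot(nxv, nyv)
        xs[i] = np.clip(px + side * off * nxv / norm, x0, x1)
        ys[i] = np.clip(py + side * off * nyv / norm, y0, y1)

    latent = areas.table["latent_deprivation"].to_numpy()
    centroids = np.array([[p.centroid.x, p.centroid.y] for p in areas.polygons])
    area_idx = np.empty(n, dtype=int)
    for i in range(n):
        hit = areas.area_index_at(xs[i], ys[i])
        if hit is None:  # offset pushed the point off the tiling edge
            hit = int(np.argmin(np.hypot(centroids[:, 0] - xs[i], centroids[:, 1] - ys[i])))
        area_idx[i] = hit
    true_raw = latent[area_idx]
    sd = true_raw.std()
    true_index = (true_raw - true_raw.mean()) / sd if sd > 1e-12 else np.zeros(n)

    age = np.clip(rng.normal(53.1, 9.3, n), 35.0, 85.0)
    female = rng.random(n) < 0.54
    bmi = np.clip(rng.normal(27.8, 5.7, n), 15.0, 55.0)
    income_cat = rng.choice(np.arange(1, 7), size=n, p=INCOME_CAT_PROBS)
    urban = rng.random(n) < 0.217
    ahei = np.clip(rng.normal(37.4, 9.9, n), 5.0, 80.0)
    met_high = rng.random(n) < 0.53
    smoker = rng.random(n) < 0.46
    drinker = rng.random(n) < 0.30

    design = {
        "age_z": (age - age.mean()) / age.std(),
        "female": female - female.mean(),
        "bmi_z": (bmi - bmi.mean()) / bmi.std(),
        "income_cat": income_cat - income_cat.mean(),
        "urban": urban - urban.mean(),
        "ahei_z": (ahei - ahei.mean()) / ahei.std(),
        "met_high": met_high - met_high.mean(),
        "smoker": smoker - smoker.mean(),
        "drinker": drinker - drinker.mean(),
    }
    linear = config.true_index_log_or * true_index
    for name, gamma in config.covariate_effects.items():
        if name not in design:
            raise InvalidConfigError(f"unknown covariate effect {name!r}")
        linear = linear + gamma * design[name]
    alpha = _calibrate_intercept(linear, config.target_prevalence)
    p = expit(alpha + linear)
    diabetes = rng.random(n) < p

    # diabetes-status inputs consistent with the drawn outcome
    self_report = diabetes & (rng.random(n) < 0.85)
    meds = diabetes & (rng.random(n) < 0.60)
    fpg = np.clip(rng.normal(5.3, 0.6, n), 3.5, 6.9)
    high_fpg = diabetes & (rng.random(n) < 0.70)
    fpg[high_fpg] = np.clip(rng.normal(8.5, 1.2, int(high_fpg.sum())), 7.0, 20.0)
    neither = diabetes & ~(self_report | meds | high_fpg)
    self_report |= neither  # every case satisfies at least one criterion

    return pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "x": xs,
            "y": ys,
            "age": age,
            "sex": np.where(female, "female", "male"),
            "bmi": bmi,
            "income_cat": income_cat,
            "urbanicity": np.where(urban, "urban", "suburban/rural"),
            "ahei": ahei,
            "met_class": np.where(met_high, ">=525", "<525"),
            "smoker": smoker.astype(int),
            "drinker": drinker.astype(int),
            "self_report_diabetes": self_report.astype(int),
            "diabetes_meds": meds.astype(int),
            "fpg_mmol_l": fpg,
            "diabetes": diabetes.astype(int),
            "true_index": true_index,
            "area_id": area_idx,
        }
    )


def one_factor_profiles(
    loadings,
    n: int,
    noise_sd: float = 0.6,
    prevalence: float = 0.1,
    beta: float = 1.0,
    seed: int = 0,
):
    """Exposure-profile matrix generated from a single latent factor.

    ``X_j = loading_j * f + noise_sd * eps_j`` with ``f ~ N(0, 1)``, plus a
    binary label drawn from a logistic model on ``f`` calibrated to the
    requested prevalence. Used by index-recovery tests, where the population
    correlation matrix (and hence the expected PC1) is known in closed form.
    Returns ``(X DataFrame, labels, f)``.
    """
    lam = np.asarray(loadings, dtype=float)
    rng = np.random.default_rng(seed)
    f = rng.standard_normal(n)
    X = np.outer(f, lam) + noise_sd * rng.standard_normal((n, lam.size))
    alpha = _calibrate_intercept(beta * f, prevalence)
    y = (rng.random(n) < expit(alpha + beta * f)).astype(int)
    cols = list(ALL_VARIABLES) if lam.size == len(ALL_VARIABLES) else [
        f"var_{j + 1}" for j in range(lam.size)
    ]
    return pd.DataFrame(X, columns=cols), y, f


@dataclass
class Scenario:
    """One generated study area: network + census areas + NDVI + cohort."""

    config: ScenarioConfig
    network: StreetNetwork
    areas: CensusAreaSet
    ndvi: Raster
    cohort: pd.DataFrame


def simulate_scenario(config: ScenarioConfig) -> Scenario:
    network = gen_street_network(config)
    areas = gen_census_areas(config)
    ndvi = gen_ndvi_raster(config, areas)
    cohort = gen_cohort(config, network, areas, ndvi)
    return Scenario(config=config, network=network, areas=areas, ndvi=ndvi, cohort=cohort)


def write_scenario(scenario: Scenario, out_dir: str | Path) -> dict[str, Path]:
    """Write all scenario layers as text formats; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "network_geojson": out / "network.geojson",
        "network_csv": out / "network_edges.csv",
        "areas_geojson": out / "census_areas.geojson",
        "areas_csv": out / "census_attributes.csv",
        "ndvi_asc": out / "ndvi.asc",
        "cohort_csv": out / "cohort.csv",
    }
    scenario.network.to_geojson(paths["network_geojson"])
    scenario.network.to_edge_csv(paths["network_csv"])
    scenario.areas.write(paths["areas_geojson"], paths["areas_csv"])
    write_asc(scenario.ndvi, paths["ndvi_asc"])
    scenario.cohort.to_csv(paths["cohort_csv"], index=False)
    return paths
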
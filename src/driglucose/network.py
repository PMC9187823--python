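"""Walkable street networks, age/sex walking speeds, isochrones and ring zones.

Exposure neighbourhoods are defined by network walking time, not by census
boundaries: from a residential origin we compute the sub-network reachable
within 2, 4, ..., 20 minutes at the person's walking speed, polygonize each
cumulative reach by buffering the covered street geometry, and difference
successive polygons into ten concentric 2-minute ring zones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import LineString, MultiLineString, Point, Polygon
from shapely.ops import substring, unary_union
from shapely.strtree import STRtree

from .io_utils import write_geojson

#: Fixed walking speed of the "standard pedestrian" used for index mapping (km/h).
STANDARD_SPEED_KMH = 4.7

#: Stated average male-female walking-speed difference (km/h).
SEX_SPEED_GAP_KMH = 0.13

# Stand-in age/sex walking-speed table (km/h): female speed per age band,
# monotone non-increasing with age; male = female + SEX_SPEED_GAP_KMH.
# Brackets the 4.7 km/h standard-pedestrian speed around midlife.
DEFAULT_FEMALE_SPEED_TABLE: tuple[tuple[float, float, float], ...] = (
    (18, 30, 4.77),
    (30, 40, 4.72),
    (40, 50, 4.66),
    (50, 60, 4.55),
    (60, 70, 4.41),
    (70, 80, 4.05),
    (80, 120, 3.37),
)


class SnapError(ValueError):
    """Origin farther from the network than the snap tolerance."""


def walking_speed(age: float, sex: str, table=None) -> float:
    """Walking speed in km/h for an adult of given age and sex.

    The default table is a documented stand-in: monotone non-increasing in
    age within sex, with a constant 0.13 km/h male-female gap. A custom
    ``table`` of ``(age_lo, age_hi, female_speed)`` rows may be supplied.
    """
    if age < 18:
        raise ValueError(f"age {age} below adult support (>= 18)")
    sex = sex.lower()
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex {sex!r}")
    table = DEFAULT_FEMALE_SPEED_TABLE if table is None else table
    for lo, hi, female_speed in table:
        if lo <= age < hi:
            return female_speed + (SEX_SPEED_GAP_KMH if sex == "male" else 0.0)
    raise ValueError(f"age {age} outside speed-table support")


@dataclass(frozen=True)
class WalkProfile:
    """Pedestrian profile: age and sex imply speed unless one is given directly."""

    age: float = 50.0
    sex: str = "female"
    speed_kmh: float | None = None

    @property
    def speed(self) -> float:
        if self.speed_kmh is not None:
            if self.speed_kmh <= 0:
                raise ValueError("speed must be positive")
            return self.speed_kmh
        return walking_speed(self.age, self.sex)

    @classmethod
    def standard(cls) -> "WalkProfile":
        """The fixed-speed standard pedestrian used for grid mapping."""
        return cls(speed_kmh=STANDARD_SPEED_KMH)


class StreetNetwork:
    """Undirected walkable graph with metric node coordinates and edge lengths."""

    def __init__(self, graph: nx.Graph, crs: str = "local-metric"):
        for u, v, d in graph.edges(data=True):
            if d.get("length", 0) <= 0:
                raise ValueError(f"edge ({u}, {v}) has non-positive length")
        self.graph = graph
        self.crs = crs
        self._edge_geoms: dict | None = None
        self._tree: STRtree | None = None
        self._tree_edges: list | None = None

    @classmethod
    def from_arrays(cls, coords: dict, edges, crs: str = "local-metric") -> "StreetNetwork":
        """Build from ``{node: (x, y)}`` and an iterable of ``(u, v)`` pairs."""
        g = nx.Graph()
        for node, (x, y) in coords.items():
            g.add_node(node, pos=(float(x), float(y)))
        for u, v in edges:
            (x1, y1), (x2, y2) = coords[u], coords[v]
            g.add_edge(u, v, length=float(np.hypot(x2 - x1, y2 - y1)))
        return cls(g, crs=crs)

    @classmethod
    def from_edge_csv(cls, path: str | Path, crs: str = "local-metric") -> "StreetNetwork":
        df = pd.read_csv(path)
        coords: dict = {}
        edges = []
        for row in df.itertuples(index=False):
            coords[row.u] = (row.ux, row.uy)
            coords[row.v] = (row.vx, row.vy)
            edges.append((row.u, row.v))
        return cls.from_arrays(coords, edges, crs=crs)

    def to_edge_csv(self, path: str | Path) -> None:
        pos = self.positions
        rows = [
            {
                "u": u, "v": v,
                "ux": pos[u][0], "uy": pos[u][1],
                "vx": pos[v][0], "vy": pos[v][1],
                "length": d["length"],
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    def to_geojson(self, path: str | Path) -> None:
        geoms = [self.edge_geoms[e] for e in self.graph.edges()]
        props = [{"u": str(u), "v": str(v)} for u, v in self.graph.edges()]
        write_geojson(path, geoms, props, crs=self.crs)

    @property
    def positions(self) -> dict:
        return nx.get_node_attributes(self.graph, "pos")

    @property
    def edge_geoms(self) -> dict:
        if self._edge_geoms is None:
            pos = self.positions
            self._edge_geoms = {
                (u, v): LineString([pos[u], pos[v]]) for u, v in self.graph.edges()
            }
        return self._edge_geoms

    def _edge_tree(self):
        if self._tree is None:
            self._tree_edges = list(self.edge_geoms)
            self._tree = STRtree([self.edge_geoms[e] for e in self._tree_edges])
        return self._tree, self._tree_edges

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)


@dataclass(frozen=True)
class SnappedOrigin:
    """A query origin projected onto the nearest network edge."""

    edge: tuple
    offset_m: float          # distance along the edge from its first node
    point: Point             # projected on-edge point
    snap_distance_m: float   # straight-line distance moved by the snap


def snap_origin(network: StreetNetwork, point, max_snap_m: float = 500.0) -> SnappedOrigin:
    """Project a point onto the nearest network edge within ``max_snap_m``.

    Raises :class:`SnapError` if the nearest edge is farther than the
    tolerance, so that unsnappable addresses are flagged rather than
    silently assigned to a distant street.
    """
    if network.graph.number_of_edges() == 0:
        raise SnapError("network has no edges")
    pt = Point(point)
    tree, edge_keys = network._edge_tree()
    idx = tree.nearest(pt)
    edge = edge_keys[idx]
    geom = network.edge_geoms[edge]
    dist = pt.distance(geom)
    if dist > max_snap_m:
        raise SnapError(
            f"nearest edge is {dist:.1f} m away (> max_snap_m = {max_snap_m} m)"
        )
    offset = geom.project(pt)
    return SnappedOrigin(
        edge=edge,
        offset_m=float(offset),
        point=geom.interpolate(offset),
        snap_distance_m=float(dist),
    )


def _node_distances(network: StreetNetwork, origin: SnappedOrigin, cutoff_m: float) -> dict:
    """Network distance from the snapped origin to every node within cutoff.

    Uses two single-source Dijkstra passes from the snapped edge's endpoints
    (offset by the along-edge distances) instead of mutating the graph.
    """
    u, v = origin.edge
    length = network.graph.edges[u, v]["length"]
    a = origin.offset_m          # origin -> u along the edge
    b = length - origin.offset_m  # origin -> v along the edge
    du = nx.single_source_dijkstra_path_length(
        network.graph, u, cutoff=max(cutoff_m - a, 0.0), weight="length"
    )
    dv = nx.single_source_dijkstra_path_length(
        network.graph, v, cutoff=max(cutoff_m - b, 0.0), weight="length"
    )
    dist: dict = {}
    for node, d in du.items():
        dist[node] = a + d
    for node, d in dv.items():
        cand = b + d
        if cand < dist.get(node, np.inf):
            dist[node] = cand
    return {n: d for n, d in dist.items() if d <= cutoff_m}


def _merge_intervals(intervals, length: float):
    clipped = []
    for lo, hi in intervals:
        lo, hi = max(lo, 0.0), min(hi, length)
        if hi > lo:
            clipped.append((lo, hi))
    clipped.sort()
    merged: list[list[float]] = []
    for lo, hi in clipped:
        if merged and lo <= merged[-1][1] + 1e-9:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return merged


@dataclass
class ReachedSet:
    """Edge fragments reachable within a network-distance cutoff."""

    cutoff_m: float
    geoms: list = field(default_factory=list)

    @property
    def geometry(self):
        return unary_union(self.geoms) if self.geoms else MultiLineString([])

    def is_empty(self) -> bool:
        return not self.geoms


def _reached_from_distances(
    network: StreetNetwork, origin: SnappedOrigin, dist: dict, cutoff_m: float
) -> ReachedSet:
    reached = ReachedSet(cutoff_m=cutoff_m)
    if cutoff_m <= 0:
        return reached
    for (p, q), geom in network.edge_geoms.items():
        length = network.graph.edges[p, q]["length"]
        intervals = []
        if (p, q) == origin.edge or (q, p) == origin.edge:
            off = origin.offset_m if (p, q) == origin.edge else length - origin.offset_m
            intervals.append((off - cutoff_m, off + cutoff_m))
        dp, dq = dist.get(p), dist.get(q)
        if dp is not None:
            intervals.append((0.0, cutoff_m - dp))
        if dq is not None:
            intervals.append((length - (cutoff_m - dq), length))
        for lo, hi in _merge_intervals(intervals, length):
            if hi - lo <= 1e-9:
                continue
            if lo <= 1e-9 and hi >= length - 1e-9:
                reached.geoms.append(geom)
            else:
                reached.geoms.append(substring(geom, lo, hi))
    return reached


def reachable_subnetwork(
    network: StreetNetwork,
    origin: SnappedOrigin,
    time_min: float,
    speed_kmh: float,
) -> ReachedSet:
    """Edge fragments within ``speed * time`` network metres of the origin.

    Partially reachable edges are split at the exact cutoff distance, so the
    returned geometry is the exact walkable trace, not a node set.
    """
    cutoff_m = speed_kmh * 1000.0 * time_min / 60.0
    if cutoff_m <= 0:
        return ReachedSet(cutoff_m=0.0)
    dist = _node_distances(network, origin, cutoff_m)
    return _reached_from_distances(network, origin, dist, cutoff_m)


def isochrone_polygon(reached: ReachedSet, buffer_m: float):
    """Dissolved buffer around the reached street geometry.

    An empty reached set yields an empty polygon (not an error); a
    non-positive buffer is rejected because the bare 1-D trace has no area.
    """
    if buffer_m <= 0:
        raise ValueError("buffer_m must be positive")
    if reached.is_empty():
        return Polygon()
    return unary_union([g.buffer(buffer_m) for g in reached.geoms])


@dataclass
class IsochroneRingSet:
    """Ten concentric walk-time ring zones around one origin.

    ``cumulative[k]`` is the isochrone polygon for ``(k+1) * increment``
    minutes; ``rings[k]`` the set difference between successive cumulative
    polygons. ``ring_mean_distance[k]`` is the representative network
    distance of ring k: walking speed times the midpoint of its time
    interval (1, 3, ..., 19 min by default), which is deterministic and
    independent of network shape.
    """

    origin: Point
    cumulative: list
    rings: list
    ring_mean_distance: np.ndarray
    speed_kmh: float
    increment_min: float
    buffer_m: float
    snap_distance_m: float = 0.0

    @property
    def n_rings(self) -> int:
        return len(self.rings)


def compute_ring_set(
    network: StreetNetwork,
    origin_point,
    profile: WalkProfile,
    increment_min: float = 2.0,
    max_time_min: float = 20.0,
    buffer_m: float = 40.0,
    max_snap_m: float = 500.0,
) -> IsochroneRingSet:
    """Compute the concentric ring zones for one origin.

    Node distances are computed once at the outermost cutoff and reused for
    every intermediate time band.
    """
    if max_time_min <= 0 or increment_min <= 0:
        raise ValueError("times must be positive")
    n = max_time_min / increment_min
    if abs(n - round(n)) > 1e-9:
        raise ValueError("max_time_min must be divisible by increment_min")
    n = int(round(n))
    speed = profile.speed
    origin = snap_origin(network, origin_point, max_snap_m=max_snap_m)
    metres_per_min = speed * 1000.0 / 60.0
    max_cutoff = metres_per_min * max_time_min
    dist = _node_distances(network, origin, max_cutoff)

    cumulative = []
    for k in range(1, n + 1):
        cutoff = metres_per_min * increment_min * k
        reached = _reached_from_distances(network, origin, dist, cutoff)
        cumulative.append(isochrone_polygon(reached, buffer_m))

    rings = [cumulative[0]]
    for k in range(1, n):
        rings.append(cumulative[k].difference(cumulative[k - 1]))

    midpoints_min = (np.arange(n) + 0.5) * increment_min
    return IsochroneRingSet(
        origin=origin.point,
        cumulative=cumulative,
        rings=rings,
        ring_mean_distance=metres_per_min * midpoints_min,
        speed_kmh=speed,
        increment_min=increment_min,
        buffer_m=buffer_m,
        snap_distance_m=origin.snap_distance_m,
    )


def write_ring_set(rs: IsochroneRingSet, path: str | Path, crs: str = "local-metric") -> None:
    props = [
        {"ring": k + 1, "mean_distance_m": float(rs.ring_mean_distance[k])}
        for k in range(rs.n_rings)
    ]
    write_geojson(path, rs.rings, props, crs=crs)
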
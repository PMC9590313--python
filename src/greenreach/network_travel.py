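"""Road-network travel times, service areas, and psychological thresholds.

Travel times are shortest paths on an undirected road graph at a constant
mode speed; each origin (cell centroid) and each park entrance snaps to its
nearest network node, with the snap distance traversed on-network at the
mode speed.  A park's time from a cell is the minimum over its entrances.
Unreachable pairs (different graph components) are marked ``inf``.

Service areas follow the paper's buffer-along-the-road logic: the set of
network locations within a park's service radius of any entrance, dilated
by a small off-road buffer so that POIs and street-view points standing
beside a covered street count as inside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import LineString, MultiLineString, Point

from .city_model import Park

UNREACHABLE = math.inf


@dataclass
class RoadNetwork:
    """Undirected road graph: nodes with planar coordinates, edges with
    measured lengths (which may exceed the straight-line chord)."""

    nodes: dict[int, tuple[float, float]]
    edges: list[tuple[int, int, float, str]]  # (u, v, length_m, road_class)

    def validate(self) -> None:
        for u, v, length, _rc in self.edges:
            if u == v:
                raise ValueError(f"self-loop at node {u}")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u},{v}) references missing node")
            if not (length > 0 and math.isfinite(length)):
                raise ValueError(f"edge ({u},{v}) has non-positive length {length}")

    def graph(self, length_attr: str = "length_m",
              allowed_classes: set[str] | None = None) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for u, v, length, rc in self.edges:
            if allowed_classes is not None and rc not in allowed_classes:
                continue
            if g.has_edge(u, v):
                if g[u][v][length_attr] <= length:
                    continue
            g.add_edge(u, v, **{length_attr: length, "road_class": rc})
        return g

    def kdtree(self) -> tuple[cKDTree, list[int]]:
        ids = sorted(self.nodes)
        pts = np.array([self.nodes[i] for i in ids])
        return cKDTree(pts), ids


@dataclass
class TravelMode:
    """A travel mode with its speed and psychological time threshold t0."""

    name: str
    speed_kmh: float
    t0_min: float
    allowed_classes: set[str] | None = None  # None = all edges

    def __post_init__(self) -> None:
        if self.speed_kmh <= 0:
            raise ValueError("speed must be > 0")
        if self.t0_min <= 0:
            raise ValueError("t0 must be > 0")

    @property
    def speed_m_per_min(self) -> float:
        return self.speed_kmh * 1000.0 / 60.0


#: Mode parameters: walking 5 km/h within 30 min, cycling 15 km/h within
#: 25 min, driving 40 km/h within 30 min.
DEFAULT_MODES: dict[str, TravelMode] = {
    "walking": TravelMode("walking", 5.0, 30.0),
    "cycling": TravelMode("cycling", 15.0, 25.0),
    "driving": TravelMode("driving", 40.0, 30.0),
}


@dataclass
class ODTimeMatrix:
    """Origin-destination travel minutes: rows = demand cells, cols = parks.

    Entries are minutes >= 0, with ``inf`` marking unreachable pairs.
    """

    minutes: np.ndarray
    cell_ids: list[int]
    park_ids: list[int]
    mode: str

    def __post_init__(self) -> None:
        finite = self.minutes[np.isfinite(self.minutes)]
        if finite.size and finite.min() < 0:
            raise ValueError("negative travel time")


def od_travel_times(
    network: RoadNetwork,
    origins: Sequence[tuple[int, tuple[float, float]]],
    parks: Sequence[Park],
    mode: TravelMode,
) -> ODTimeMatrix:
    """Compute the cell x park travel-time matrix for one mode.

    ``origins`` is a sequence of ``(cell_id, (x, y))``.  For each park a
    single-source Dijkstra runs from a virtual node linked to every entrance
    via its snap distance, so the matrix costs one graph traversal per park.
    """
    if not network.nodes:
        raise ValueError("empty road network")
    speed = mode.speed_m_per_min
    g = network.graph(allowed_classes=mode.allowed_classes)
    tree, ids = network.kdtree()

    origin_xy = np.array([xy for _cid, xy in origins])
    snap_d, snap_i = tree.query(origin_xy)
    origin_nodes = [ids[i] for i in snap_i]

    n_cells, n_parks = len(origins), len(parks)
    minutes = np.full((n_cells, n_parks), UNREACHABLE)
    virtual = max(network.nodes) + 1
    for j, park in enumerate(parks):
        exy = np.array(park.entrances, dtype=float)
        ed, ei = tree.query(exy)
        g.add_node(virtual)
        for d, i in zip(np.atleast_1d(ed), np.atleast_1d(ei)):
            node = ids[int(i)]
            off = float(d) / speed  # minutes to walk/ride the snap gap
            if not g.has_edge(virtual, node) or g[virtual][node]["length_m"] > off * speed:
                g.add_edge(virtual, node, length_m=off * speed)
        dist = nx.single_source_dijkstra_path_length(g, virtual, weight="length_m")
        g.remove_node(virtual)
        for i_row, node in enumerate(origin_nodes):
            if node in dist:
                minutes[i_row, j] = dist[node] / speed + snap_d[i_row] / speed
    return ODTimeMatrix(
        minutes=minutes,
        cell_ids=[cid for cid, _ in origins],
        park_ids=[p.park_id for p in parks],
        mode=mode.name,
    )


@dataclass
class ServiceArea:
    """Network locations within a park's service radius of its entrances,
    dilated by an off-road buffer for point-membership tests."""

    covered: MultiLineString
    buffer_m: float

    def contains(self, point: tuple[float, float]) -> bool:
        if self.covered.is_empty:
            return False
        return self.covered.distance(Point(point)) <= self.buffer_m + 1e-9

    def contains_many(self, points: np.ndarray) -> np.ndarray:
        return np.array([self.contains(tuple(p)) for p in points], dtype=bool)


def network_service_area(
    network: RoadNetwork,
    park: Park,
    buffer_m: float = 20.0,
) -> ServiceArea:
    """Build the park's service area: road segments within network distance
    ``park.service_radius_m`` of any entrance.

    Edge geometry is the straight chord between node coordinates; partially
    covered edges are cut at the fraction of measured length the remaining
    budget allows.
    """
    if park.service_radius_m is None:
        raise ValueError(f"park {park.park_id}: service radius not assigned")
    radius = float(park.service_radius_m)
    g = network.graph()
    tree, ids = network.kdtree()

    # multi-source Dijkstra with per-entrance snap offsets via a virtual node
    virtual = max(network.nodes) + 1
    g.add_node(virtual)
    exy = np.array(park.entrances, dtype=float)
    ed, ei = tree.query(exy)
    for d, i in zip(np.atleast_1d(ed), np.atleast_1d(ei)):
        node = ids[int(i)]
        if not g.has_edge(virtual, node) or g[virtual][node]["length_m"] > float(d):
            g.add_edge(virtual, node, length_m=float(d))
    dist = nx.single_source_dijkstra_path_length(
        g, virtual, weight="length_m", cutoff=radius
    )
    g.remove_node(virtual)
    dist.pop(virtual, None)

    segments: list[LineString] = []
    for u, v, data in g.edges(data=True):
        length = data["length_m"]
        pu, pv = network.nodes[u], network.nodes[v]
        ru = radius - dist[u] if u in dist else -1.0
        rv = radius - dist[v] if v in dist else -1.0
        if ru >= length or rv >= length or (ru >= 0 and rv >= 0 and ru + rv >= length):
            segments.append(LineString([pu, pv]))
            continue
        if ru > 0:
            f = ru / length
            segments.append(LineString([pu, _lerp(pu, pv, f)]))
        if rv > 0:
            f = rv / length
            segments.append(LineString([pv, _lerp(pv, pu, f)]))
    covered = MultiLineString(segments) if segments else MultiLineString([])
    return ServiceArea(covered=covered, buffer_m=buffer_m)


def _lerp(a: tuple[float, float], b: tuple[float, float], f: float) -> tuple[float, float]:
    return (a[0] + f * (b[0] - a[0]), a[1] + f * (b[1] - a[1]))


# ---------------------------------------------------------------------------
# Survey-derived psychological time thresholds
# ---------------------------------------------------------------------------

@dataclass
class SurveyBins:
    """Willingness-to-travel survey: per (park category, mode) shares of
    respondents in ordered travel-time bins.

    ``midpoints_min`` holds the bin midpoints in minutes; the open top bin
    ("over 60 min") is represented by its fixed 60-minute midpoint.
    ``shares`` maps ``(park_category, mode_name)`` to per-bin fractions
    that must sum to 1.
    """

    midpoints_min: Sequence[float]
    shares: Mapping[tuple[str, str], Sequence[float]]

    def validate(self) -> None:
        for key, pct in self.shares.items():
            if len(pct) != len(self.midpoints_min):
                raise ValueError(f"{key}: {len(pct)} shares for "
                                 f"{len(self.midpoints_min)} bins")
            if abs(sum(pct) - 1.0) > 1e-9:
                raise ValueError(f"{key}: shares sum to {sum(pct)}, not 1")


def threshold_from_survey(bins: SurveyBins) -> dict[str, float]:
    """Derive per-mode psychological thresholds t0 from survey bins.

    Per (category, mode) the mean willing travel time is the share-weighted
    sum of bin midpoints; per mode, t0 is the maximum of those means over
    the four park categories, rounded half-up to a whole minute — so the
    threshold accommodates the park type people travel furthest for.
    """
    bins.validate()
    mids = np.asarray(bins.midpoints_min, dtype=float)
    best: dict[str, float] = {}
    for (_category, mode_name), pct in bins.shares.items():
        mean = float(np.dot(mids, np.asarray(pct, dtype=float)))
        best[mode_name] = max(best.get(mode_name, -math.inf), mean)
    return {m: float(math.floor(v + 0.5)) for m, v in best.items()}
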
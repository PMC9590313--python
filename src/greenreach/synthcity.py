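"""Seeded generator of synthetic ring-structured cities.

The generator emulates the statistical structure the accessibility
analysis assumes about a dense monocentric city: concentric ring zones, a
population surface decaying from the centre (delivered through
residential-POI-based dasymetric redistribution), parks of four categories
with size-dependent service radii and multiple entrances snapped to the
road network, a lattice road network with diagonal shortcuts and an
optional river gap, service-function POIs clustered around parks, and a
smooth green-view field in [0, 1].

Every layer draws from its own named stream spawned from one master seed,
so layers can be regenerated independently and the whole city is
deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .city_model import (
    POI_CATEGORIES,
    CityModel,
    DemandCell,
    GreenViewSample,
    POIRecord,
    Park,
    assign_service_radius,
    build_grid,
    redistribute_population,
    _square_around,
)
from .network_travel import RoadNetwork

_LAYERS = ("network", "parks", "pois", "residential", "greenview")

#: Default park counts per category for the ~25 km² baseline city.
DEFAULT_PARK_COUNTS = {"comprehensive": 2, "special": 3, "community": 7, "street": 8}

#: Log-normal area parameters (mean of log m², sd of log) per category,
#: spanning large comprehensive parks down to 0.1-ha street gardens.
DEFAULT_PARK_AREAS = {
    "comprehensive": (math.log(150_000), 0.35),
    "special": (math.log(20_000), 0.9),
    "community": (math.log(12_000), 0.45),
    "street": (math.log(2_500), 0.35),
}


@dataclass
class ScenarioSpec:
    """Parameters of a synthetic city.

    Defaults model a 5 x 5 km monocentric urban core at 100 m grid
    resolution with 250 000 residents (10 000 persons/km², a typical
    inner-city density), three ring zones, 20 parks and a 100 m lattice
    road network.
    """

    nrows: int = 50
    ncols: int = 50
    cell_size_m: float = 100.0
    ring_radii_m: tuple[float, ...] = (800.0, 1600.0)
    total_population: float = 250_000.0
    pop_decay_m: float = 2000.0
    park_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PARK_COUNTS))
    park_areas: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PARK_AREAS)
    )
    max_entrances: int = 4
    network_spacing_cells: int = 1
    diagonal_frac: float = 0.05
    river_gap: bool = False
    bridge_every: int = 8
    n_pois: int = 1200
    n_residential_pois: int = 800
    poi_cluster_frac: float = 0.6
    greenview_base: float = 0.25
    greenview_amp: float = 0.35
    greenview_bumps: int = 12
    greenview_scale_m: float = 900.0
    greenway_boost: float = 0.0
    park_free_quadrant: str | None = None  # e.g. "NE"
    seed: int = 0

    def validate(self) -> None:
        if self.nrows < 10 or self.ncols < 10:
            raise ValueError("grid must be at least 10 x 10 cells")
        n_parks = sum(self.park_counts.values())
        if n_parks > self.nrows * self.ncols:
            raise ValueError("more parks than grid cells")
        if n_parks < 1:
            raise ValueError("need at least one park")
        for k, v in self.park_counts.items():
            if v < 0:
                raise ValueError(f"negative park count for {k}")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (0.0, 0.0, self.ncols * self.cell_size_m, self.nrows * self.cell_size_m)

    @property
    def center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.extent
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


def _rng(spec: ScenarioSpec, layer: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(_LAYERS.index(layer),))
    )


def generate_city(spec: ScenarioSpec) -> CityModel:
    """Generate a full synthetic city; deterministic given ``spec.seed``."""
    spec.validate()
    extent = spec.extent
    cx, cy = spec.center

    grid = build_grid(extent, spec.cell_size_m)
    radii = list(spec.ring_radii_m)
    for cell in grid:
        d = math.hypot(cell.centroid[0] - cx, cell.centroid[1] - cy)
        ring = sum(d > r for r in radii) + 1
        cell.zone = f"ring-{ring}"

    network = _make_network(spec)
    node_xy = np.array([network.nodes[i] for i in sorted(network.nodes)])

    parks = _make_parks(spec, node_xy)
    residential = _make_residential_pois(spec)
    pois = _make_service_pois(spec, parks)
    greenview = _make_greenview(spec, network)

    zone_totals = _zone_totals(spec, grid)
    redistribute_population(zone_totals, grid, residential, spec.cell_size_m)

    city = CityModel(
        grid=grid,
        parks=parks,
        network=network,
        pois=pois + residential,
        greenview=greenview,
        crs_note="synthetic planar metres, origin at SW corner",
        cell_size_m=spec.cell_size_m,
        extent=extent,
        zone_totals=zone_totals,
    )
    city.validate()
    return city


def _zone_totals(spec: ScenarioSpec, grid: Sequence[DemandCell]) -> dict[str, float]:
    """Split the total population over ring zones in proportion to an
    exponentially decaying density surface."""
    cx, cy = spec.center
    weights: dict[str, float] = {}
    for cell in grid:
        d = math.hypot(cell.centroid[0] - cx, cell.centroid[1] - cy)
        weights[cell.zone] = weights.get(cell.zone, 0.0) + math.exp(-d / spec.pop_decay_m)
    total_w = sum(weights.values())
    return {z: spec.total_population * w / total_w for z, w in sorted(weights.items())}


def _make_network(spec: ScenarioSpec) -> RoadNetwork:
    rng = _rng(spec, "network")
    step = spec.network_spacing_cells * spec.cell_size_m
    nx_nodes = spec.ncols // spec.network_spacing_cells + 1
    ny_nodes = spec.nrows // spec.network_spacing_cells + 1
    nodes: dict[int, tuple[float, float]] = {}
    for r in range(ny_nodes):
        for c in range(nx_nodes):
            nodes[r * nx_nodes + c] = (c * step, r * step)

    _, _, _, ymax = spec.extent
    river_y = ymax / 2.0
    edges: list[tuple[int, int, float, str]] = []
    for r in range(ny_nodes):
        for c in range(nx_nodes):
            nid = r * nx_nodes + c
            if c + 1 < nx_nodes:
                edges.append((nid, nid + 1, step, "street"))
            if r + 1 < ny_nodes:
                y0, y1 = r * step, (r + 1) * step
                crosses = spec.river_gap and y0 < river_y <= y1
                if crosses and c % spec.bridge_every != 0:
                    continue
                cls = "bridge" if crosses else "street"
                edges.append((nid, nid + nx_nodes, step, cls))
    # diagonal shortcuts through a random subset of lattice squares
    n_squares = (nx_nodes - 1) * (ny_nodes - 1)
    n_diag = int(spec.diagonal_frac * n_squares)
    if n_diag:
        picks = rng.choice(n_squares, size=n_diag, replace=False)
        for s in picks:
            r, c = divmod(int(s), nx_nodes - 1)
            y0, y1 = r * step, (r + 1) * step
            if spec.river_gap and y0 < river_y <= y1:
                continue
            a = r * nx_nodes + c
            b = (r + 1) * nx_nodes + c + 1
            edges.append((a, b, step * math.sqrt(2.0), "shortcut"))
    return RoadNetwork(nodes=nodes, edges=edges)


def _make_parks(spec: ScenarioSpec, node_xy: np.ndarray) -> list[Park]:
    rng = _rng(spec, "parks")
    x0, y0, x1, y1 = spec.extent
    cx, cy = spec.center
    parks: list[Park] = []
    pid = 0
    for category in ("comprehensive", "special", "community", "street"):
        count = spec.park_counts.get(category, 0)
        mu, sigma = spec.park_areas[category]
        for _ in range(count):
            area = float(np.clip(rng.lognormal(mu, sigma), 1000.0, None))
            side = math.sqrt(area)
            margin = side / 2.0 + spec.cell_size_m
            for _attempt in range(200):
                px = rng.uniform(x0 + margin, x1 - margin)
                py = rng.uniform(y0 + margin, y1 - margin)
                if spec.park_free_quadrant and _in_quadrant(
                    (px, py), spec.park_free_quadrant, (cx, cy), side
                ):
                    continue
                break
            poly = _square_around((px, py), side)
            n_ent = int(rng.integers(1, spec.max_entrances + 1))
            # entrances: boundary midpoints snapped to the nearest road node
            bpts = _boundary_points(poly, n_ent)
            ent: list[tuple[float, float]] = []
            for bp in bpts:
                d2 = ((node_xy - np.asarray(bp)) ** 2).sum(axis=1)
                snap = tuple(float(v) for v in node_xy[int(d2.argmin())])
                if snap not in ent:
                    ent.append(snap)
            park = Park(park_id=pid, category=category, area_m2=area,
                        entrances=ent, polygon=poly)
            park.service_radius_m = assign_service_radius(park)
            parks.append(park)
            pid += 1
    return parks


def _in_quadrant(p: tuple[float, float], quad: str,
                 center: tuple[float, float], pad: float = 0.0) -> bool:
    cx, cy = center
    east = p[0] + pad > cx if "E" in quad else p[0] - pad < cx
    north = p[1] + pad > cy if "N" in quad else p[1] - pad < cy
    return east and north


def _boundary_points(poly: Sequence[tuple[float, float]], k: int) -> list[tuple[float, float]]:
    corners = poly[:-1]
    mids = [((a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0)
            for a, b in zip(poly[:-1], poly[1:])]
    return (mids + list(corners))[:k]


def _make_residential_pois(spec: ScenarioSpec) -> list[POIRecord]:
    """Residence-type POIs: density decays exponentially from the centre
    (sampled by rejection), mirroring a monocentric population surface."""
    rng = _rng(spec, "residential")
    x0, y0, x1, y1 = spec.extent
    cx, cy = spec.center
    out: list[POIRecord] = []
    next_id = 100_000
    while len(out) < spec.n_residential_pois:
        px = rng.uniform(x0, x1)
        py = rng.uniform(y0, y1)
        if rng.random() < math.exp(-math.hypot(px - cx, py - cy) / spec.pop_decay_m):
            out.append(POIRecord(poi_id=next_id, location=(px, py),
                                 category="living_service", residential=True))
            next_id += 1
    return out


def _make_service_pois(spec: ScenarioSpec, parks: Sequence[Park]) -> list[POIRecord]:
    """Service-function POIs in the 13 categories: a clustered fraction
    around park surroundings, the rest uniform over the city."""
    rng = _rng(spec, "pois")
    x0, y0, x1, y1 = spec.extent
    cat_p = rng.dirichlet(np.full(len(POI_CATEGORIES), 4.0))
    out: list[POIRecord] = []
    centers = [p.polygon[0] if p.polygon else p.entrances[0] for p in parks]
    for i in range(spec.n_pois):
        if parks and rng.random() < spec.poi_cluster_frac:
            cxp, cyp = centers[int(rng.integers(len(centers)))]
            sd = 400.0
            px = float(np.clip(rng.normal(cxp, sd), x0, x1))
            py = float(np.clip(rng.normal(cyp, sd), y0, y1))
        else:
            px, py = rng.uniform(x0, x1), rng.uniform(y0, y1)
        cat = POI_CATEGORIES[int(rng.choice(len(POI_CATEGORIES), p=cat_p))]
        out.append(POIRecord(poi_id=i, location=(px, py), category=cat))
    return out


def _make_greenview(spec: ScenarioSpec, network: RoadNetwork) -> list[GreenViewSample]:
    """Green-view samples at road nodes: a smooth bump field in [0, 1],
    optionally elevated along the riverside greenway."""
    rng = _rng(spec, "greenview")
    x0, y0, x1, y1 = spec.extent
    bumps = [(rng.uniform(x0, x1), rng.uniform(y0, y1), rng.uniform(-1.0, 1.0))
             for _ in range(spec.greenview_bumps)]
    river_y = (y0 + y1) / 2.0
    out: list[GreenViewSample] = []
    for nid in sorted(network.nodes):
        x, y = network.nodes[nid]
        f = spec.greenview_base
        for bx, by, amp in bumps:
            d2 = (x - bx) ** 2 + (y - by) ** 2
            f += spec.greenview_amp * amp * math.exp(-d2 / (2 * spec.greenview_scale_m ** 2))
        if spec.greenway_boost and abs(y - river_y) < 150.0:
            f += spec.greenway_boost
        f = float(np.clip(f, 0.0, 1.0))
        heads = np.clip(f + rng.normal(0.0, 0.03, size=4), 0.0, 1.0)
        out.append(GreenViewSample(sample_id=nid, location=(x, y),
                                   vegetation_fractions=tuple(float(h) for h in heads)))
    return out


# ---------------------------------------------------------------------------
# Named scenarios
# ---------------------------------------------------------------------------

SCENARIOS = ("baseline", "park_desert_quadrant", "riverside_greenway",
             "uniform_everything")


def make_scenario(name: str, seed: int = 0) -> CityModel:
    """Build one of the named test scenarios.

    ``baseline`` is the default ring city; ``park_desert_quadrant`` places
    no park in the NE quadrant; ``riverside_greenway`` adds a river gap
    with bridges and a greenway green-view boost; ``uniform_everything``
    is the analytic limit with identical parks on a symmetric lattice and
    uniform population.
    """
    if name == "baseline":
        return generate_city(ScenarioSpec(seed=seed))
    if name == "park_desert_quadrant":
        return generate_city(ScenarioSpec(seed=seed, park_free_quadrant="NE"))
    if name == "riverside_greenway":
        return generate_city(
            ScenarioSpec(seed=seed, river_gap=True, greenway_boost=0.25)
        )
    if name == "uniform_everything":
        return _uniform_city(seed)
    raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")


def _uniform_city(seed: int) -> CityModel:
    """Symmetric limit: identical community parks on a 4 x 4 lattice,
    uniform population, constant green view, no service POIs."""
    spec = ScenarioSpec(seed=seed, park_counts={"community": 0}, n_pois=0,
                        n_residential_pois=0)
    extent = spec.extent
    grid = build_grid(extent, spec.cell_size_m)
    for cell in grid:
        cell.zone = "ring-1"
        cell.population = spec.total_population / len(grid)
    network = _make_network(
        ScenarioSpec(seed=seed, diagonal_frac=0.0)
    )
    node_xy = np.array([network.nodes[i] for i in sorted(network.nodes)])
    parks = []
    pid = 0
    x0, y0, x1, y1 = extent
    for r in range(4):
        for c in range(4):
            px = x0 + (c + 0.5) * (x1 - x0) / 4.0
            py = y0 + (r + 0.5) * (y1 - y0) / 4.0
            area = 10_000.0
            poly = _square_around((px, py), math.sqrt(area))
            ent = []
            for bp in _boundary_points(poly, 4):
                d2 = ((node_xy - np.asarray(bp)) ** 2).sum(axis=1)
                snap = tuple(float(v) for v in node_xy[int(d2.argmin())])
                if snap not in ent:
                    ent.append(snap)
            park = Park(park_id=pid, category="community", area_m2=area,
                        entrances=ent, polygon=poly)
            park.service_radius_m = assign_service_radius(park)
            parks.append(park)
            pid += 1
    greenview = [
        GreenViewSample(sample_id=nid, location=network.nodes[nid],
                        vegetation_fractions=(0.5, 0.5, 0.5, 0.5))
        for nid in sorted(network.nodes)
    ]
    return CityModel(
        grid=grid, parks=parks, network=network, pois=[], greenview=greenview,
        crs_note="synthetic planar metres, uniform limit",
        cell_size_m=spec.cell_size_m, extent=extent,
        zone_totals={"ring-1": spec.total_population},
    )
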
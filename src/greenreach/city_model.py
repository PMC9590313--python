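"""Domain types and I/O for the synthetic-or-real city model.

A *city* bundles everything the accessibility pipeline consumes: a demand
grid of 100 m cells carrying population, park polygons with entrance points,
an undirected road network, points of interest (POIs) in thirteen
service-function categories, and street-level green-view samples.  All
geometries live in one projected planar frame in metres; no CRS
transformations are performed.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

#: The closed set of service-function categories used for the
#: Shannon-Wiener diversity of a park's surroundings.
POI_CATEGORIES: tuple[str, ...] = (
    "scenic_spot",
    "catering",
    "public_facility",
    "transportation_facility",
    "company_enterprise",
    "shopping",
    "accommodation",
    "science_education_culture",
    "government_social_organization",
    "healthcare",
    "sports_leisure",
    "living_service",
    "financial_service",
)

PARK_CATEGORIES: tuple[str, ...] = ("comprehensive", "special", "community", "street")

#: Parks below this area (0.1 ha) are not counted as public parks.
MIN_PARK_AREA_M2 = 1000.0

#: Special parks larger than this get the wider 500 m service radius.
SPECIAL_PARK_AREA_CUT_M2 = 5000.0


class CityModelError(ValueError):
    """Raised when a city component violates a model invariant."""


@dataclass
class DemandCell:
    """One square demand unit of the analysis grid.

    Attributes
    ----------
    cell_id : int
        Unique, 0-based, row-major over the grid.
    centroid : (float, float)
        Planar coordinates (m) of the cell's (possibly clipped) centre.
    population : float
        Residents assigned to the cell, >= 0.
    zone : str | None
        Optional ring-zone label (e.g. ``"ring-1"``).
    partial : bool
        True for edge cells clipped by the study-area extent.
    area_m2 : float
        True (clipped) cell area.
    row, col : int
        Lattice indices, row-major from the lower-left corner.
    """

    cell_id: int
    centroid: tuple[float, float]
    population: float = 0.0
    zone: str | None = None
    partial: bool = False
    area_m2: float = 0.0
    row: int = 0
    col: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.population) or self.population < 0:
            raise CityModelError(
                f"cell {self.cell_id}: population must be finite and >= 0, "
                f"got {self.population}"
            )


@dataclass
class Park:
    """An urban park acting as a supply point (via its entrances)."""

    park_id: int
    category: str
    area_m2: float
    entrances: list[tuple[float, float]]
    polygon: list[tuple[float, float]] | None = None
    service_radius_m: float | None = None

    def __post_init__(self) -> None:
        if self.category not in PARK_CATEGORIES:
            raise CityModelError(
                f"park {self.park_id}: unknown category {self.category!r}; "
                f"expected one of {PARK_CATEGORIES}"
            )
        if not self.area_m2 >= MIN_PARK_AREA_M2:
            raise CityModelError(
                f"park {self.park_id}: area {self.area_m2} m² below the "
                f"{MIN_PARK_AREA_M2:.0f} m² (0.1 ha) floor"
            )
        if len(self.entrances) < 1:
            raise CityModelError(f"park {self.park_id}: needs at least one entrance")


@dataclass
class POIRecord:
    """A point of interest in one of the 13 service-function categories."""

    poi_id: int
    location: tuple[float, float]
    category: str
    residential: bool = False

    def __post_init__(self) -> None:
        if self.category not in POI_CATEGORIES:
            raise CityModelError(
                f"POI {self.poi_id}: category {self.category!r} not in the "
                f"closed 13-label set"
            )


@dataclass
class GreenViewSample:
    """Street-level vegetation fractions at four compass headings."""

    sample_id: int
    location: tuple[float, float]
    vegetation_fractions: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        for f in self.vegetation_fractions:
            if not (0.0 <= f <= 1.0):
                raise CityModelError(
                    f"green-view sample {self.sample_id}: fraction {f} "
                    f"outside [0, 1]"
                )

    @property
    def green_view_index(self) -> float:
        """Mean vegetation fraction over the four headings."""
        return sum(self.vegetation_fractions) / 4.0


@dataclass
class CityModel:
    """Container bundling every input layer of the analysis."""

    grid: list[DemandCell]
    parks: list["Park"]
    network: "RoadNetwork"
    pois: list[POIRecord]
    greenview: list[GreenViewSample]
    crs_note: str = "synthetic planar metres"
    cell_size_m: float = 100.0
    extent: tuple[float, float, float, float] | None = None
    zone_totals: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        ids = [c.cell_id for c in self.grid]
        if len(ids) != len(set(ids)):
            raise CityModelError("duplicate cell_id in grid")
        pids = [p.park_id for p in self.parks]
        if len(pids) != len(set(pids)):
            raise CityModelError("duplicate park_id")
        self.network.validate()


# ---------------------------------------------------------------------------
# Grid construction and population redistribution
# ---------------------------------------------------------------------------

def build_grid(
    extent: tuple[float, float, float, float],
    cell_size_m: float = 100.0,
) -> list[DemandCell]:
    """Tile a bounding box with square demand cells, row-major.

    Partial edge cells (where the extent is not an exact multiple of the
    cell size) are included, flagged, and carry their true clipped area.

    Parameters
    ----------
    extent : (xmin, ymin, xmax, ymax)
        Planar bounding box in metres; must be non-degenerate.
    cell_size_m : float
        Cell edge length, default 100 m.
    """
    xmin, ymin, xmax, ymax = extent
    if cell_size_m <= 0:
        raise ValueError(f"cell_size_m must be > 0, got {cell_size_m}")
    if xmax <= xmin or ymax <= ymin:
        raise ValueError(f"degenerate extent {extent}")
    ncols = math.ceil((xmax - xmin) / cell_size_m - 1e-12)
    nrows = math.ceil((ymax - ymin) / cell_size_m - 1e-12)
    cells: list[DemandCell] = []
    cid = 0
    for r in range(nrows):
        y0 = ymin + r * cell_size_m
        y1 = min(y0 + cell_size_m, ymax)
        for c in range(ncols):
            x0 = xmin + c * cell_size_m
            x1 = min(x0 + cell_size_m, xmax)
            w, h = x1 - x0, y1 - y0
            partial = (w < cell_size_m - 1e-9) or (h < cell_size_m - 1e-9)
            cells.append(
                DemandCell(
                    cell_id=cid,
                    centroid=((x0 + x1) / 2.0, (y0 + y1) / 2.0),
                    partial=partial,
                    area_m2=w * h,
                    row=r,
                    col=c,
                )
            )
            cid += 1
    return cells


def redistribute_population(
    zone_totals: Mapping[str, float],
    grid: Sequence[DemandCell],
    pois: Sequence[POIRecord],
    cell_size_m: float = 100.0,
    integer: bool = False,
) -> list[DemandCell]:
    """Spread zone population totals over cells proportionally to
    residential-POI counts (dasymetric redistribution).

    Within each zone the population is split in proportion to the number of
    residential POIs falling in each cell; zones with no residential POI at
    all fall back to a uniform split.  Zone totals are conserved exactly —
    with ``integer=True`` via largest-remainder rounding.
    """
    for z, tot in zone_totals.items():
        if tot < 0:
            raise ValueError(f"zone {z!r}: negative total {tot}")
    for cell in grid:
        if cell.zone is None or cell.zone not in zone_totals:
            raise ValueError(
                f"cell {cell.cell_id}: zone {cell.zone!r} not in zone_totals"
            )

    counts = {cell.cell_id: 0 for cell in grid}
    cell_index: dict[tuple[int, int], DemandCell] = {}
    # cells are addressed by lattice position derived from their centroid
    for cell in grid:
        cell_index[(cell.row, cell.col)] = cell
    x0 = min(c.centroid[0] - cell_size_m / 2 for c in grid)
    y0 = min(c.centroid[1] - cell_size_m / 2 for c in grid)
    for poi in pois:
        if not poi.residential:
            continue
        col = int((poi.location[0] - x0) // cell_size_m)
        row = int((poi.location[1] - y0) // cell_size_m)
        cell = cell_index.get((row, col))
        if cell is not None:
            counts[cell.cell_id] += 1

    for zone, total in zone_totals.items():
        zcells = [c for c in grid if c.zone == zone]
        if not zcells:
            continue
        zcounts = [counts[c.cell_id] for c in zcells]
        csum = sum(zcounts)
        if csum == 0:
            shares = [total / len(zcells)] * len(zcells)
        else:
            shares = [total * k / csum for k in zcounts]
        if integer:
            shares = _largest_remainder(shares, round(total))
        for cell, p in zip(zcells, shares):
            cell.population = float(p)
    return list(grid)


def _largest_remainder(shares: Sequence[float], total: int) -> list[int]:
    floors = [int(math.floor(s)) for s in shares]
    deficit = total - sum(floors)
    order = sorted(
        range(len(shares)), key=lambda i: shares[i] - floors[i], reverse=True
    )
    out = list(floors)
    for i in order[:deficit]:
        out[i] += 1
    return out


def assign_service_radius(park: Park) -> float:
    """Service radius by park category and size.

    Comprehensive parks, and special parks above 5 000 m², serve 500 m of
    network; smaller special parks, community parks and street gardens serve
    300 m.  The tie at exactly 5 000 m² resolves upward to 500 m.
    """
    if park.category not in PARK_CATEGORIES:
        raise ValueError(f"unknown park category {park.category!r}")
    if park.category == "comprehensive":
        return 500.0
    if park.category == "special":
        return 500.0 if park.area_m2 >= SPECIAL_PARK_AREA_CUT_M2 else 300.0
    return 300.0


# ---------------------------------------------------------------------------
# File I/O (GeoJSON + CSV bundle)
# ---------------------------------------------------------------------------

def save_city(city: CityModel, directory: str | Path) -> None:
    """Write a city as a GeoJSON/CSV bundle under ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    feats = []
    for p in city.parks:
        poly = p.polygon or _square_around(_centroid(p.entrances), math.sqrt(p.area_m2))
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [[list(pt) for pt in poly]]},
                "properties": {
                    "park_id": p.park_id,
                    "category": p.category,
                    "area_m2": p.area_m2,
                    "entrances": [list(e) for e in p.entrances],
                    "service_radius_m": p.service_radius_m,
                },
            }
        )
    _write_geojson(d / "parks.geojson", feats)

    feats = []
    for q in city.pois:
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": list(q.location)},
                "properties": {
                    "poi_id": q.poi_id,
                    "category": q.category,
                    "residential": q.residential,
                },
            }
        )
    _write_geojson(d / "pois.geojson", feats)

    with open(d / "grid.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cell_id", "row", "col", "x", "y", "population", "zone",
                    "partial", "area_m2"])
        for c in city.grid:
            w.writerow([c.cell_id, c.row, c.col, c.centroid[0], c.centroid[1],
                        repr(c.population), c.zone or "", int(c.partial), c.area_m2])

    with open(d / "network_nodes.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["node_id", "x", "y"])
        for nid, (x, y) in sorted(city.network.nodes.items()):
            w.writerow([nid, x, y])
    with open(d / "network_edges.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["u", "v", "length_m", "road_class"])
        for u, v, length, rc in city.network.edges:
            w.writerow([u, v, length, rc])

    with open(d / "greenview.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "x", "y", "f0", "f90", "f180", "f270"])
        for s in city.greenview:
            w.writerow([s.sample_id, s.location[0], s.location[1],
                        *s.vegetation_fractions])

    meta = {
        "crs_note": city.crs_note,
        "cell_size_m": city.cell_size_m,
        "extent": list(city.extent) if city.extent else None,
        "zone_totals": {k: float(v) for k, v in city.zone_totals.items()},
    }
    with open(d / "config.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def load_city(directory: str | Path) -> CityModel:
    """Read a city bundle written by :func:`save_city`, validating schemas.

    Raises
    ------
    CityModelError
        Naming the offending file and field on any schema violation.
    """
    from .network_travel import RoadNetwork

    d = Path(directory)
    with open(d / "config.yaml") as fh:
        meta = yaml.safe_load(fh)

    parks = []
    for feat in _read_geojson(d / "parks.geojson"):
        props = feat["properties"]
        try:
            poly = [tuple(pt) for pt in feat["geometry"]["coordinates"][0]]
            parks.append(
                Park(
                    park_id=int(props["park_id"]),
                    category=props["category"],
                    area_m2=float(props["area_m2"]),
                    entrances=[tuple(e) for e in props["entrances"]],
                    polygon=poly,
                    service_radius_m=props.get("service_radius_m"),
                )
            )
        except (KeyError, CityModelError) as exc:
            raise CityModelError(f"parks.geojson: {exc}") from exc

    pois = []
    for feat in _read_geojson(d / "pois.geojson"):
        props = feat["properties"]
        try:
            pois.append(
                POIRecord(
                    poi_id=int(props["poi_id"]),
                    location=tuple(feat["geometry"]["coordinates"]),
                    category=props["category"],
                    residential=bool(props["residential"]),
                )
            )
        except (KeyError, CityModelError) as exc:
            raise CityModelError(f"pois.geojson: {exc}") from exc

    grid = []
    with open(d / "grid.csv", newline="") as fh:
        for rec in csv.DictReader(fh):
            grid.append(
                DemandCell(
                    cell_id=int(rec["cell_id"]),
                    row=int(rec["row"]),
                    col=int(rec["col"]),
                    centroid=(float(rec["x"]), float(rec["y"])),
                    population=float(rec["population"]),
                    zone=rec["zone"] or None,
                    partial=bool(int(rec["partial"])),
                    area_m2=float(rec["area_m2"]),
                )
            )

    nodes: dict[int, tuple[float, float]] = {}
    with open(d / "network_nodes.csv", newline="") as fh:
        for rec in csv.DictReader(fh):
            nodes[int(rec["node_id"])] = (float(rec["x"]), float(rec["y"]))
    edges = []
    with open(d / "network_edges.csv", newline="") as fh:
        for rec in csv.DictReader(fh):
            edges.append(
                (int(rec["u"]), int(rec["v"]), float(rec["length_m"]),
                 rec["road_class"])
            )
    network = RoadNetwork(nodes=nodes, edges=edges)

    greenview = []
    with open(d / "greenview.csv", newline="") as fh:
        for rec in csv.DictReader(fh):
            try:
                greenview.append(
                    GreenViewSample(
                        sample_id=int(rec["sample_id"]),
                        location=(float(rec["x"]), float(rec["y"])),
                        vegetation_fractions=(
                            float(rec["f0"]), float(rec["f90"]),
                            float(rec["f180"]), float(rec["f270"]),
                        ),
                    )
                )
            except CityModelError as exc:
                raise CityModelError(f"greenview.csv: {exc}") from exc

    city = CityModel(
        grid=grid,
        parks=parks,
        network=network,
        pois=pois,
        greenview=greenview,
        crs_note=meta.get("crs_note", ""),
        cell_size_m=float(meta.get("cell_size_m", 100.0)),
        extent=tuple(meta["extent"]) if meta.get("extent") else None,
        zone_totals=dict(meta.get("zone_totals", {})),
    )
    city.validate()
    return city


def save_outputs(results: Mapping[str, "object"], directory: str | Path) -> None:
    """Write per-cell / per-park result tables as CSV (DataFrames) or text."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name, obj in results.items():
        if hasattr(obj, "to_csv"):
            obj.to_csv(d / f"{name}.csv", index=False)
        else:
            with open(d / f"{name}.txt", "w") as fh:
                fh.write(str(obj) + "\n")


def _write_geojson(path: Path, features: list[dict]) -> None:
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def _read_geojson(path: Path) -> list[dict]:
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise CityModelError(f"{path.name}: not a FeatureCollection")
    return data["features"]


def _centroid(pts: Iterable[tuple[float, float]]) -> tuple[float, float]:
    pts = list(pts)
    return (sum(p[0] for p in pts) / len(pts), sum(p[1] for p in pts) / len(pts))


def _square_around(center: tuple[float, float], side: float) -> list[tuple[float, float]]:
    cx, cy = center
    h = side / 2.0
    return [(cx - h, cy - h), (cx + h, cy - h), (cx + h, cy + h),
            (cx - h, cy + h), (cx - h, cy - h)]
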
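"""Farm layout, local planar projection and the 3 x 3 m occupancy grid.

The farm is modelled in a local planar frame (meters east/north of a
projection origin).  Because the whole site spans only a few hundred
meters, a local equirectangular projection about the farm centroid is
used: distortion relative to great-circle distances is far below GPS
noise at this scale.

Coordinates, polygons and the grid all live in this planar frame; raw
logger records carry geodetic latitude/longitude and are projected on
ingestion.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon, box, mapping, shape

#: mean Earth radius in meters (IUGG R1)
EARTH_RADIUS_M = 6_371_008.8

#: maximum angular offset from the projection origin accepted by the
#: projection (about 5.5 km) -- farm-scale points only
MAX_OFFSET_DEG = 0.05

#: resource-location labels; PADDOCK and PASTURE are the residual areas
RESOURCE_LABELS = (
    [f"FS_{i}" for i in range(1, 8)]
    + [f"CF_{i}" for i in range(1, 4)]
    + [f"LH_{i}" for i in range(1, 4)]
    + ["RF_1", "RF_2", "SH_1", "SH_2", "TR_1", "TR_2"]
)
LOCATION_LABELS = RESOURCE_LABELS + ["PADDOCK", "PASTURE"]


class OutOfRangeError(ValueError):
    """A geodetic point is too far from the projection origin."""


class OutOfGridError(ValueError):
    """A planar point lies outside the grid extent."""


class UnassignedSquareError(ValueError):
    """A grid square's center is in neither paddock nor pasture."""


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def project_to_local(lat, lon, origin):
    """Project geodetic coordinates to local planar meters.

    Equirectangular about ``origin = (lat0, lon0)``:
    ``x = R cos(lat0) (lon - lon0)``, ``y = R (lat - lat0)`` (radians).

    Accepts scalars or arrays; raises :class:`OutOfRangeError` for points
    more than 0.05 degrees from the origin.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    lat0, lon0 = origin
    dlat = lat - lat0
    dlon = lon - lon0
    if np.any(np.abs(dlat) >= MAX_OFFSET_DEG) or np.any(np.abs(dlon) >= MAX_OFFSET_DEG):
        raise OutOfRangeError(
            "point(s) more than %.2f deg from the projection origin" % MAX_OFFSET_DEG
        )
    x = EARTH_RADIUS_M * math.cos(math.radians(lat0)) * np.radians(dlon)
    y = EARTH_RADIUS_M * np.radians(dlat)
    if x.ndim == 0:
        return float(x), float(y)
    return x, y


def unproject_from_local(x, y, origin):
    """Inverse of :func:`project_to_local` (exact round-trip)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lat0, lon0 = origin
    lat = lat0 + np.degrees(y / EARTH_RADIUS_M)
    lon = lon0 + np.degrees(x / (EARTH_RADIUS_M * math.cos(math.radians(lat0))))
    if lat.ndim == 0:
        return float(lat), float(lon)
    return lat, lon


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in meters on the mean-radius sphere.

    Vectorised; this is the geodesic used to recompute step distances.
    """
    p1 = np.radians(np.asarray(lat1, dtype=float))
    p2 = np.radians(np.asarray(lat2, dtype=float))
    dp = p2 - p1
    dl = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

@dataclass
class PastureArea:
    """One pasture polygon with its availability calendar.

    ``open_days`` is a list of inclusive ``(first_day, last_day)`` ranges of
    1-based observation-day indices during which this pasture is open.
    """

    polygon: Polygon
    open_days: list[tuple[int, int]] = field(default_factory=list)

    def is_open(self, day: int) -> bool:
        return any(a <= day <= b for a, b in self.open_days)


@dataclass
class FarmLayout:
    """Planar farm geometry: paddock, pastures and labelled resource zones."""

    paddock_polygon: Polygon
    pasture_areas: list[PastureArea]
    resource_zones: dict[str, Polygon]
    projection_origin: tuple[float, float]
    bbox_margin_m: float = 15.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for label, poly in self.resource_zones.items():
            if label not in RESOURCE_LABELS:
                raise ValueError(f"unknown resource label {label!r}")
            if not self.paddock_polygon.contains(poly):
                raise ValueError(f"resource zone {label} is not inside the paddock")
        for pa in self.pasture_areas:
            if pa.polygon.intersection(self.paddock_polygon).area > 0:
                raise ValueError("pasture polygon overlaps the paddock interior")

    @property
    def pasture_polygons(self) -> list[Polygon]:
        return [pa.polygon for pa in self.pasture_areas]

    def pasture_union(self):
        return shapely.union_all(self.pasture_polygons) if self.pasture_areas else Polygon()

    def farm_union(self):
        return shapely.union_all([self.paddock_polygon] + self.pasture_polygons)

    def open_pastures(self, day: int) -> list[PastureArea]:
        return [pa for pa in self.pasture_areas if pa.is_open(day)]

    def planar_bounds(self) -> tuple[float, float, float, float]:
        return self.farm_union().bounds

    def bounding_box_geodetic(self) -> tuple[float, float, float, float]:
        """(min_lat, max_lat, min_lon, max_lon) of the farm plus margin.

        This is the "most northern/eastern/western/southern position of the
        farm" box used by the first filtering stage.
        """
        minx, miny, maxx, maxy = self.planar_bounds()
        m = self.bbox_margin_m
        lat_min, lon_min = unproject_from_local(minx - m, miny - m, self.projection_origin)
        lat_max, lon_max = unproject_from_local(maxx + m, maxy + m, self.projection_origin)
        return lat_min, lat_max, lon_min, lon_max

    # -- serialisation ------------------------------------------------------

    def to_geojson(self) -> dict:
        feats = [
            {
                "type": "Feature",
                "properties": {"label": "PADDOCK"},
                "geometry": mapping(self.paddock_polygon),
            }
        ]
        for pa in self.pasture_areas:
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"label": "PASTURE", "open_days": [list(r) for r in pa.open_days]},
                    "geometry": mapping(pa.polygon),
                }
            )
        for label, poly in self.resource_zones.items():
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"label": label},
                    "geometry": mapping(poly),
                }
            )
        return {
            "type": "FeatureCollection",
            "properties": {
                "projection_origin": list(self.projection_origin),
                "bbox_margin_m": self.bbox_margin_m,
            },
            "features": feats,
        }

    @classmethod
    def from_geojson(cls, doc: dict) -> "FarmLayout":
        paddock = None
        pastures: list[PastureArea] = []
        zones: dict[str, Polygon] = {}
        for feat in doc["features"]:
            label = feat["properties"]["label"]
            poly = shape(feat["geometry"])
            if label == "PADDOCK":
                paddock = poly
            elif label == "PASTURE":
                ranges = [tuple(r) for r in feat["properties"].get("open_days", [])]
                pastures.append(PastureArea(poly, ranges))
            else:
                zones[label] = poly
        if paddock is None:
            raise ValueError("layout document has no PADDOCK feature")
        props = doc.get("properties", {})
        return cls(
            paddock_polygon=paddock,
            pasture_areas=pastures,
            resource_zones=zones,
            projection_origin=tuple(props["projection_origin"]),
            bbox_margin_m=props.get("bbox_margin_m", 15.0),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "FarmLayout":
        with open(path) as fh:
            return cls.from_geojson(json.load(fh))


def default_farm_layout(summer_days: int = 159) -> FarmLayout:
    """Synthetic active-stable layout emulating a ~1 ha paddock.

    The paddock is a 120 x 90 m rectangle holding seven hay feed stalls,
    three concentrate stalls, three lying halls (LH_1 the large "metal"
    hall, LH_2/LH_3 tarp-skin), two straw racks, two shelters and two
    troughs.  Two pastures adjoin the east fence; each is open for half
    of the summer (pastures were rotated with the stock of grass).
    This is a synthetic stand-in layout: the real farm's geometry is not
    published.
    """
    half = summer_days // 2
    paddock = box(0, 0, 120, 90)
    pastures = [
        PastureArea(box(120, 0, 240, 44), [(1, half)]),
        PastureArea(box(120, 46, 240, 90), [(half + 1, summer_days)]),
    ]
    zones = {
        "LH_1": box(10, 5, 35, 15),     # 250 m2 metal hall, south
        "LH_2": box(10, 70, 26, 80),    # 160 m2 tarp skin
        "LH_3": box(30, 70, 46, 80),    # 160 m2 tarp skin
        "FS_1": box(5, 30, 11, 36),
        "FS_2": box(5, 40, 11, 46),
        "FS_3": box(5, 50, 11, 56),
        "FS_4": box(50, 5, 56, 11),
        "FS_5": box(55, 80, 70, 88),    # ad libitum hay area, far north
        "FS_6": box(100, 70, 108, 76),  # new roughage stalls, north-east
        "FS_7": box(100, 60, 108, 66),
        "CF_1": box(60, 40, 66, 46),
        "CF_2": box(70, 40, 76, 46),
        "CF_3": box(80, 40, 86, 46),
        "RF_1": box(40, 30, 46, 36),
        "RF_2": box(75, 65, 81, 71),
        "SH_1": box(90, 5, 98, 13),
        "SH_2": box(110, 30, 118, 38),
        "TR_1": box(30, 50, 34, 53),
        "TR_2": box(112, 80, 116, 83),  # next to the pasture access
    }
    return FarmLayout(
        paddock_polygon=paddock,
        pasture_areas=pastures,
        resource_zones=zones,
        projection_origin=(54.30, 9.10),
    )


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SquareId:
    row: int
    col: int


@dataclass(frozen=True)
class GridSpec:
    """Regular square grid anchored at the farm bounding box SW corner.

    Cells are half-open ``[x0 + c*s, x0 + (c+1)*s) x [y0 + r*s, y0 + (r+1)*s)``
    so every interior point belongs to exactly one cell and a point on a
    shared edge belongs to the higher-index cell.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @classmethod
    def from_layout(cls, layout: FarmLayout, cell_size: float = 3.0) -> "GridSpec":
        minx, miny, maxx, maxy = layout.planar_bounds()
        # one extra cell so the closed upper boundary is covered too
        n_cols = int(math.floor((maxx - minx) / cell_size)) + 1
        n_rows = int(math.floor((maxy - miny) / cell_size)) + 1
        return cls(minx, miny, cell_size, n_rows, n_cols)

    def cell_center(self, square: SquareId) -> tuple[float, float]:
        s = self.cell_size
        return (
            self.origin_x + (square.col + 0.5) * s,
            self.origin_y + (square.row + 0.5) * s,
        )

    def encode(self, rows, cols):
        """Pack (row, col) into a single integer square code."""
        return np.asarray(rows) * self.n_cols + np.asarray(cols)

    def decode(self, codes):
        codes = np.asarray(codes)
        return codes // self.n_cols, codes % self.n_cols


def square_of(x, y, grid: GridSpec):
    """Map planar point(s) to grid cell indices (row, col).

    Scalars return a :class:`SquareId`; arrays return ``(rows, cols)``
    integer arrays.  Points outside the grid extent raise
    :class:`OutOfGridError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    col = np.floor((x - grid.origin_x) / grid.cell_size).astype(np.int64)
    row = np.floor((y - grid.origin_y) / grid.cell_size).astype(np.int64)
    bad = (row < 0) | (row >= grid.n_rows) | (col < 0) | (col >= grid.n_cols)
    if np.any(bad):
        raise OutOfGridError("point(s) outside the grid extent")
    if x.ndim == 0:
        return SquareId(int(row), int(col))
    return row, col


def assign_label_grid(layout: FarmLayout, grid: GridSpec) -> np.ndarray:
    """Label every grid cell by the zone containing its center.

    Returns an ``(n_rows, n_cols)`` object array of location labels;
    cells whose center falls in neither paddock nor pasture hold ``None``.
    Resource zones take precedence over the residual PADDOCK/PASTURE
    labels; zones are tested in a fixed label order for determinism.
    """
    rows, cols = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij")
    cx = grid.origin_x + (cols + 0.5) * grid.cell_size
    cy = grid.origin_y + (rows + 0.5) * grid.cell_size
    labels = np.full((grid.n_rows, grid.n_cols), None, dtype=object)
    unset = np.ones(labels.shape, dtype=bool)
    for label in RESOURCE_LABELS:
        poly = layout.resource_zones.get(label)
        if poly is None:
            continue
        hit = shapely.intersects_xy(poly, cx, cy) & unset
        labels[hit] = label
        unset &= ~hit
    hit = shapely.intersects_xy(layout.paddock_polygon, cx, cy) & unset
    labels[hit] = "PADDOCK"
    unset &= ~hit
    for pa in layout.pasture_areas:
        hit = shapely.intersects_xy(pa.polygon, cx, cy) & unset
        labels[hit] = "PASTURE"
        unset &= ~hit
    return labels


def location_of(square: SquareId, layout: FarmLayout, grid: GridSpec,
                label_grid: np.ndarray | None = None) -> str:
    """Location label of one square (by cell-center containment)."""
    if label_grid is not None:
        label = label_grid[square.row, square.col]
    else:
        cx, cy = grid.cell_center(square)
        label = None
        for lab in RESOURCE_LABELS:
            poly = layout.resource_zones.get(lab)
            if poly is not None and shapely.intersects_xy(poly, cx, cy):
                label = lab
                break
        if label is None and shapely.intersects_xy(layout.paddock_polygon, cx, cy):
            label = "PADDOCK"
        if label is None:
            for pa in layout.pasture_areas:
                if shapely.intersects_xy(pa.polygon, cx, cy):
                    label = "PASTURE"
                    break
    if label is None:
        raise UnassignedSquareError(
            f"square ({square.row}, {square.col}) is in neither paddock nor pasture"
        )
    return label
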
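"""Geographic context: analysis grid, distance/coverage rasters, and binning.

Every run is enriched at its start cell with 22 geographic features: the
Euclidean distance (m) to the nearest cell of each of the 9 landuse classes,
the coverage percentage of each class within a 10x10-cell (1 km^2 at the
default 100 m resolution) window, and the 4 demographic attributes of the
neighborhood polygon containing the start point.

Continuous geographic features are discretized against the *reference*
distribution over all grid cells of the study landscape: a dedicated "0"
category plus 10 equal-probability (decile) bins over the strictly positive
values, mirroring how national-scale priors turn raw meters or percentages
into interpretable rarity classes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import Point

from .features import (
    COVERAGE_FEATURES,
    DEMOGRAPHIC_FEATURES,
    DISTANCE_FEATURES,
    HOUR_BINS,
    HUMIDITY_TYPES,
    LANDUSE_CLASSES,
    LANDUSE_CODE,
    MONTHS,
    TEMPERATURE_BINS,
    WEATHER_TYPES,
    WEEKDAYS,
    WIND_TYPES,
)

logger = logging.getLogger(__name__)

GEO_FEATURES = DISTANCE_FEATURES + COVERAGE_FEATURES + DEMOGRAPHIC_FEATURES

_FIXED_VOCABULARY = {
    "hour": HOUR_BINS,
    "weekday": WEEKDAYS,
    "month": MONTHS,
    "temperature": TEMPERATURE_BINS,
    "weather": WEATHER_TYPES,
    "wind": WIND_TYPES,
    "humidity": HUMIDITY_TYPES,
}


@dataclass(frozen=True)
class Grid:
    """Regular analysis grid in a planar metric CRS.

    ``origin`` is the lower-left corner; cell ``(row, col)`` covers the ground
    rectangle ``[origin_x + col*s, origin_x + (col+1)*s) x [origin_y + row*s,
    origin_y + (row+1)*s)`` and its center is ``origin + (col+0.5, row+0.5)*s``.
    """

    origin: tuple[float, float]
    cell_size: float
    width: int
    height: int

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.width < 1 or self.height < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def n_cells(self) -> int:
        return self.width * self.height

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the covered rectangle."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.width * self.cell_size, y0 + self.height * self.cell_size)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 + (row + 0.5) * self.cell_size)

    def cell_of(self, x, y):
        """Vectorized point -> (rows, cols, inside-mask)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        cols = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        rows = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        inside = (cols >= 0) & (cols < self.width) & (rows >= 0) & (rows < self.height)
        return rows, cols, inside


def build_grid(extent: tuple[float, float, float, float], cell_size: float = 100.0) -> Grid:
    """Build the analysis grid covering ``extent = (xmin, ymin, xmax, ymax)``.

    Width and height are ceilings of the extent size over ``cell_size`` so the
    grid always covers the extent.
    """
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("extent must have positive area")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    width = int(np.ceil((xmax - xmin) / cell_size))
    height = int(np.ceil((ymax - ymin) / cell_size))
    return Grid(origin=(float(xmin), float(ymin)), cell_size=float(cell_size), width=width, height=height)


@dataclass
class LanduseRaster:
    """Integer-coded landuse classes on a :class:`Grid` (codes 1..9)."""

    grid: Grid
    classes: np.ndarray  # (height, width) int codes

    def __post_init__(self):
        self.classes = np.asarray(self.classes)
        if self.classes.shape != (self.grid.height, self.grid.width):
            raise ValueError("class array shape does not match grid")
        if not np.isin(self.classes, np.arange(1, len(LANDUSE_CLASSES) + 1)).all():
            raise ValueError("class codes must be in 1..9")

    def mask(self, landuse_class: str) -> np.ndarray:
        return self.classes == LANDUSE_CODE[landuse_class]

    def present_classes(self) -> set[str]:
        codes = np.unique(self.classes)
        return {LANDUSE_CLASSES[c - 1] for c in codes}


@dataclass
class ClassRaster:
    """A per-cell scalar derived for one landuse class (distance or coverage)."""

    grid: Grid
    landuse_class: str
    values: np.ndarray


def distance_to_class(landuse: LanduseRaster, landuse_class: str) -> ClassRaster:
    """Per-cell Euclidean distance (m) to the nearest cell of ``landuse_class``.

    Distances are center-to-center at the raster resolution; cells of the
    class itself are at distance 0 (running *on* the class surface).
    """
    if landuse_class not in LANDUSE_CODE:
        raise ValueError(f"unknown landuse class {landuse_class!r}")
    mask = landuse.mask(landuse_class)
    if not mask.any():
        raise ValueError(f"class {landuse_class!r} absent from raster; distance undefined")
    dist = ndimage.distance_transform_edt(~mask, sampling=landuse.grid.cell_size)
    return ClassRaster(grid=landuse.grid, landuse_class=landuse_class, values=dist)


def _window_bounds(row: int, col: int, height: int, width: int, window: int):
    # A window x window block with no exact center cell: rows [r - w/2, r + w/2 - 1].
    half = window // 2
    r0, r1 = max(0, row - half), min(height, row + window - half)
    c0, c1 = max(0, col - half), min(width, col + window - half)
    return r0, r1, c0, c1


def coverage_percent(
    landuse: LanduseRaster, landuse_class: str, cell_index: tuple[int, int], window: int = 10
) -> float:
    """Coverage % of a class in the ``window x window`` block around one cell.

    The block spans rows ``[r-5, r+4]`` and cols ``[c-5, c+4]`` for the default
    10-cell window, clipped at raster borders with the denominator reduced to
    the cells actually inside the raster.
    """
    row, col = cell_index
    if not (0 <= row < landuse.grid.height and 0 <= col < landuse.grid.width):
        raise ValueError("cell_index outside grid")
    mask = landuse.mask(landuse_class)
    r0, r1, c0, c1 = _window_bounds(row, col, landuse.grid.height, landuse.grid.width, window)
    block = mask[r0:r1, c0:c1]
    return 100.0 * block.sum() / block.size


def coverage_raster(landuse: LanduseRaster, landuse_class: str, window: int = 10) -> ClassRaster:
    """Coverage % of a class for every cell, via an integral image."""
    if landuse_class not in LANDUSE_CODE:
        raise ValueError(f"unknown landuse class {landuse_class!r}")
    mask = landuse.mask(landuse_class).astype(np.int64)
    h, w = mask.shape
    integral = np.zeros((h + 1, w + 1), dtype=np.int64)
    integral[1:, 1:] = mask.cumsum(0).cumsum(1)
    half = window // 2
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    r0 = np.clip(rows - half, 0, h)
    r1 = np.clip(rows + window - half, 0, h)
    c0 = np.clip(cols - half, 0, w)
    c1 = np.clip(cols + window - half, 0, w)
    r0b = np.broadcast_to(r0, (h, w))
    r1b = np.broadcast_to(r1, (h, w))
    c0b = np.broadcast_to(c0, (h, w))
    c1b = np.broadcast_to(c1, (h, w))
    counts = (
        integral[r1b, c1b] - integral[r0b, c1b] - integral[r1b, c0b] + integral[r0b, c0b]
    )
    sizes = (r1b - r0b) * (c1b - c0b)
    return ClassRaster(grid=landuse.grid, landuse_class=landuse_class, values=100.0 * counts / sizes)


class BinningScheme:
    """Discretization of all 29 features into categorical items.

    Temporal and weather features carry fixed vocabularies; the 22 geographic
    features carry a dedicated ``"0"`` category plus up to 10 decile bins over
    the strictly positive reference distribution (duplicate decile edges are
    merged, so discrete distributions yield fewer, well-defined bins).
    """

    def __init__(self, geo_edges: dict[str, list[float]]):
        unknown = set(geo_edges) - set(GEO_FEATURES)
        if unknown:
            raise ValueError(f"unknown geographic features: {sorted(unknown)}")
        self.geo_edges = {f: [float(e) for e in geo_edges.get(f, [])] for f in GEO_FEATURES}
        for f, edges in self.geo_edges.items():
            if any(b <= a for a, b in zip(edges, edges[1:])):
                raise ValueError(f"{f}: bin edges must be strictly increasing")
        self._geo_labels = {f: self._labels_for(edges) for f, edges in self.geo_edges.items()}

    @staticmethod
    def _labels_for(edges: list[float]) -> tuple[str, ...]:
        labels = ["0"]
        prev = 0.0
        for e in edges:
            labels.append(f"({prev:g},{e:g}]")
            prev = e
        return tuple(labels)

    def categories(self, feature: str) -> tuple[str, ...]:
        if feature in _FIXED_VOCABULARY:
            return _FIXED_VOCABULARY[feature]
        if feature in self._geo_labels:
            return self._geo_labels[feature]
        raise KeyError(f"unknown feature {feature!r}")

    def bin_geo_value(self, feature: str, value: float) -> str:
        """Bin one geographic value; values above the reference max clamp into the top bin."""
        edges = self.geo_edges[feature]
        labels = self._geo_labels[feature]
        if value < 0:
            raise ValueError(f"{feature}: negative value {value}")
        if value == 0 or not edges:
            return labels[0]
        idx = int(np.searchsorted(edges, value, side="left"))
        return labels[min(idx + 1, len(labels) - 1)]

    def bin_geo_values(self, feature: str, values: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`bin_geo_value` over an array."""
        edges = np.asarray(self.geo_edges[feature])
        labels = np.asarray(self._geo_labels[feature], dtype=object)
        values = np.asarray(values, dtype=float)
        if (values < 0).any():
            raise ValueError(f"{feature}: negative values")
        if edges.size == 0:
            return np.full(values.shape, "0", dtype=object)
        idx = np.searchsorted(edges, values, side="left") + 1
        idx = np.minimum(idx, len(labels) - 1)
        idx[values == 0] = 0
        return labels[idx]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"geo_edges": self.geo_edges}, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BinningScheme":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(json.loads(text)["geo_edges"])


def nearest_rank_deciles(values: np.ndarray) -> list[float]:
    """Decile edges of the strictly positive values by the nearest-rank method.

    Edge k (k = 1..10) is the value at rank ``ceil(k * n / 10)`` of the sorted
    positive sample; duplicates are merged. The 10th edge is the maximum, which
    closes the top bin.
    """
    pos = np.sort(np.asarray(values, dtype=float)[np.asarray(values) > 0])
    n = pos.size
    if n == 0:
        return []
    ranks = np.ceil(np.arange(1, 11) * n / 10.0).astype(int) - 1
    edges = []
    for e in pos[ranks]:
        if not edges or e > edges[-1]:
            edges.append(float(e))
    return edges


def national_quantile_bins(values_by_feature: dict[str, np.ndarray]) -> BinningScheme:
    """Build the :class:`BinningScheme` from reference cell distributions.

    Each geographic feature gets a "0" category plus decile bins over its
    positive values; a feature whose reference values are all zero collapses
    to the single "0" category (logged).
    """
    geo_edges = {}
    for feature, values in values_by_feature.items():
        edges = nearest_rank_deciles(np.asarray(values))
        if not edges:
            logger.warning("%s: all reference values are zero; single '0' category", feature)
        geo_edges[feature] = edges
    return BinningScheme(geo_edges)


def demographics_at(point: Point | tuple[float, float], neighborhoods: pd.DataFrame):
    """Demographic attributes of the neighborhood polygon containing ``point``.

    Boundary points are assigned to the first covering polygon in table order.
    Returns ``None`` (missing-context signal) when no polygon covers the point;
    the caller is expected to drop the run.
    """
    if len(neighborhoods) == 0:
        raise ValueError("neighborhood table is empty")
    if not isinstance(point, Point):
        point = Point(*point)
    for _, row in neighborhoods.iterrows():
        if row["geometry"].covers(point):
            return {f: row[f] for f in DEMOGRAPHIC_FEATURES}
    return None


@dataclass
class GeoContextStack:
    """Precomputed per-cell context: distances, coverages and demographics.

    ``demographics`` holds one (height, width) array per attribute with NaN on
    cells whose center falls outside every neighborhood polygon.
    """

    landuse: LanduseRaster
    distances: dict[str, ClassRaster]
    coverages: dict[str, ClassRaster]
    neighborhoods: pd.DataFrame
    demographics: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def build(cls, landuse: LanduseRaster, neighborhoods: pd.DataFrame, window: int = 10) -> "GeoContextStack":
        distances = {}
        for c in LANDUSE_CLASSES:
            if landuse.mask(c).any():
                distances[c] = distance_to_class(landuse, c)
        coverages = {c: coverage_raster(landuse, c, window=window) for c in LANDUSE_CLASSES}
        demographics = _rasterize_demographics(landuse.grid, neighborhoods)
        return cls(
            landuse=landuse,
            distances=distances,
            coverages=coverages,
            neighborhoods=neighborhoods,
            demographics=demographics,
        )

    def reference_values(self) -> dict[str, np.ndarray]:
        """Flattened per-cell value distributions used to fit the binning scheme."""
        out = {}
        for c in LANDUSE_CLASSES:
            if c in self.distances:
                out[f"dist_{c}"] = self.distances[c].values.ravel()
            else:
                # class absent from the landscape: no finite reference distances
                out[f"dist_{c}"] = np.array([])
            out[f"cov_{c}"] = self.coverages[c].values.ravel()
        for f in DEMOGRAPHIC_FEATURES:
            vals = self.demographics[f].ravel()
            out[f] = vals[~np.isnan(vals)]
        return out

    def fit_bins(self) -> BinningScheme:
        ref = self.reference_values()
        return national_quantile_bins(ref)

    def geo_values_at(self, rows: np.ndarray, cols: np.ndarray) -> pd.DataFrame:
        """Raw 22 geographic values for cell indices (vectorized).

        Distances for classes absent from the landscape come back as NaN, as do
        demographics outside every polygon; NaN marks missing context.
        """
        data = {}
        for c in LANDUSE_CLASSES:
            if c in self.distances:
                data[f"dist_{c}"] = self.distances[c].values[rows, cols]
            else:
                data[f"dist_{c}"] = np.full(len(rows), np.nan)
            data[f"cov_{c}"] = self.coverages[c].values[rows, cols]
        for f in DEMOGRAPHIC_FEATURES:
            data[f] = self.demographics[f][rows, cols]
        return pd.DataFrame(data)


def _rasterize_demographics(grid: Grid, neighborhoods: pd.DataFrame) -> dict[str, np.ndarray]:
    """Point-in-polygon query of every cell center; first covering polygon wins."""
    xs = grid.origin[0] + (np.arange(grid.width) + 0.5) * grid.cell_size
    ys = grid.origin[1] + (np.arange(grid.height) + 0.5) * grid.cell_size
    xx, yy = np.meshgrid(xs, ys)
    poly_idx = np.full((grid.height, grid.width), -1, dtype=int)
    for i, geom in enumerate(neighborhoods["geometry"]):
        unassigned = poly_idx == -1
        if not unassigned.any():
            break
        hit = shapely.intersects_xy(geom, xx[unassigned], yy[unassigned])
        idx = np.where(unassigned)
        poly_idx[idx[0][hit], idx[1][hit]] = i
    out = {}
    for f in DEMOGRAPHIC_FEATURES:
        vals = neighborhoods[f].to_numpy(dtype=float)
        arr = np.full((grid.height, grid.width), np.nan)
        inside = poly_idx >= 0
        arr[inside] = vals[poly_idx[inside]]
        out[f] = arr
    return out
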
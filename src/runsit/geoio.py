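"""Raster and vector file IO.

Rasters are written as single-band GeoTIFF using ``tifffile`` with the
standard GeoTIFF georeferencing tags (ModelPixelScale, ModelTiepoint); vector
neighborhood tables are written as GeoJSON FeatureCollections via shapely.
All coordinates live in one planar metric CRS; the raster array convention is
``array[row, col]`` with row 0 at the *southern* edge (origin = lower-left
corner), so a cell center sits at ``origin + (col + 0.5, row + 0.5) * cell_size``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping, shape

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


def write_geotiff(path: str | Path, array: np.ndarray, origin: tuple[float, float], cell_size: float) -> None:
    """Write a 2-D array as a single-band GeoTIFF.

    The array is stored north-up (TIFF row 0 = northern edge), so it is
    flipped vertically on write; :func:`read_geotiff` flips it back.
    """
    arr = np.asarray(array)
    if arr.ndim != 2:
        raise ValueError("raster must be 2-D")
    height = arr.shape[0]
    y_top = origin[1] + height * cell_size
    tifffile.imwrite(
        str(path),
        arr[::-1],
        extratags=[
            (_MODEL_PIXEL_SCALE, "d", 3, (float(cell_size), float(cell_size), 0.0)),
            (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(origin[0]), float(y_top), 0.0)),
        ],
    )


def read_geotiff(path: str | Path) -> tuple[np.ndarray, tuple[float, float], float]:
    """Read a single-band GeoTIFF written by :func:`write_geotiff`.

    Returns ``(array, origin, cell_size)`` in the lower-left row-0 convention.
    """
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        tags = {t.code: t.value for t in page.tags.values()}
    if _MODEL_PIXEL_SCALE not in tags or _MODEL_TIEPOINT not in tags:
        raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
    sx, sy = tags[_MODEL_PIXEL_SCALE][:2]
    if abs(sx - sy) > 1e-9:
        raise ValueError("non-square cells are not supported")
    x0 = tags[_MODEL_TIEPOINT][3]
    y_top = tags[_MODEL_TIEPOINT][4]
    origin = (float(x0), float(y_top) - arr.shape[0] * float(sx))
    return arr[::-1].copy(), origin, float(sx)


def write_neighborhoods_geojson(path: str | Path, table: pd.DataFrame) -> None:
    """Write a neighborhood table (shapely ``geometry`` column + attributes) as GeoJSON."""
    features = []
    for _, row in table.iterrows():
        props = {k: (v.item() if isinstance(v, np.generic) else v) for k, v in row.items() if k != "geometry"}
        features.append({"type": "Feature", "geometry": mapping(row["geometry"]), "properties": props})
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=1))


def read_neighborhoods_geojson(path: str | Path) -> pd.DataFrame:
    data = json.loads(Path(path).read_text())
    rows = []
    for feat in data["features"]:
        row = dict(feat.get("properties") or {})
        row["geometry"] = shape(feat["geometry"])
        rows.append(row)
    df = pd.DataFrame(rows)
    cols = [c for c in df.columns if c != "geometry"] + ["geometry"]
    return df[cols]
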
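"""Minimal georeferencing and raster/vector I/O.

Rasters are stored as TIFF files with the north-up affine transform, CRS
code, band names and nodata value serialised as JSON in the image
description tag.  Vectors are GeoJSON read and written through shapely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
import tifffile
from shapely.geometry import mapping, shape

DEFAULT_CRS = "EPSG:32629"  # UTM 29N


@dataclass(frozen=True)
class GridTransform:
    """North-up affine georeference of a raster grid.

    ``x0, y0`` is the map coordinate of the top-left corner of the
    top-left pixel; ``px`` is the square pixel size in metres.
    """

    x0: float
    y0: float
    px: float

    def pixel_centres(self, shape_hw: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (xs, ys) of every pixel centre, as H x W arrays."""
        h, w = shape_hw
        xs = self.x0 + (np.arange(w) + 0.5) * self.px
        ys = self.y0 - (np.arange(h) + 0.5) * self.px
        return np.broadcast_to(xs, (h, w)), np.broadcast_to(ys[:, None], (h, w))

    def refine(self, ratio: int) -> "GridTransform":
        """Transform of the same extent sampled ``ratio`` x finer."""
        return GridTransform(self.x0, self.y0, self.px / ratio)

    def extent(self, shape_hw: tuple[int, int]) -> tuple[float, float, float, float]:
        h, w = shape_hw
        return (self.x0, self.y0 - h * self.px, self.x0 + w * self.px, self.y0)


def write_raster(
    path: str | Path,
    data: np.ndarray,
    transform: GridTransform,
    *,
    crs: str = DEFAULT_CRS,
    band_names: list[str] | None = None,
    nodata: float | None = None,
) -> None:
    """Write a (H, W) or (H, W, B) array as a georeferenced TIFF."""
    data = np.asarray(data)
    meta = {
        "transform": [transform.x0, transform.y0, transform.px],
        "crs": crs,
        "band_names": band_names,
        "nodata": nodata,
    }
    kw = {}
    if data.ndim == 3:  # band-sequential layout
        data = np.moveaxis(data, 2, 0)
        kw = {"photometric": "minisblack", "planarconfig": "separate"}
    tifffile.imwrite(path, data, description=json.dumps(meta), **kw)


def read_raster(path: str | Path) -> tuple[np.ndarray, GridTransform, dict]:
    """Read a raster written by :func:`write_raster`.

    Returns the array ((H, W) or (H, W, B)), its transform and the raw
    metadata dict.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc) if desc else {}
    t = meta.get("transform", [0.0, 0.0, 1.0])
    if data.ndim == 3:
        data = np.moveaxis(data, 0, 2)
    return data, GridTransform(*t), meta


def write_geojson(path: str | Path, geom, *, properties: dict | None = None) -> None:
    feature = {
        "type": "Feature",
        "geometry": mapping(geom),
        "properties": properties or {},
    }
    obj = {"type": "FeatureCollection", "features": [feature]}
    Path(path).write_text(json.dumps(obj))


def write_geojson_features(path: str | Path, items: list[tuple[object, dict]]) -> None:
    feats = [
        {"type": "Feature", "geometry": mapping(g), "properties": p} for g, p in items
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_geojson(path: str | Path):
    """Read the first geometry of a GeoJSON file (Feature or collection)."""
    obj = json.loads(Path(path).read_text())
    if obj["type"] == "FeatureCollection":
        return shape(obj["features"][0]["geometry"])
    if obj["type"] == "Feature":
        return shape(obj["geometry"])
    return shape(obj)


def line_side(line: shapely.LineString, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Signed side of each point relative to the direction of travel.

    Positive values are on the left bank, negative on the right.  The side
    is taken against the local tangent at the nearest point on the line.
    """
    pts = shapely.points(xs, ys)
    s = shapely.line_locate_point(line, pts)
    eps = 1e-6 * line.length
    ahead = shapely.line_interpolate_point(line, np.minimum(s + eps, line.length))
    behind = shapely.line_interpolate_point(line, np.maximum(s - eps, 0.0))
    tx = shapely.get_x(ahead) - shapely.get_x(behind)
    ty = shapely.get_y(ahead) - shapely.get_y(behind)
    proj = shapely.line_interpolate_point(line, s)
    dx = xs - shapely.get_x(proj)
    dy = ys - shapely.get_y(proj)
    return tx * dy - ty * dx
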
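"""Region-of-interest quantification on 2D parameter maps.

Mirrors what the imaging device's report view does: a manually drawn
polygon on a parameter map (StO2/NPI/THI/TWI on 0-100 scales, 0.1 mm/pixel
by default) is rasterized to a pixel mask and summarised as mean, SD,
pixel count and a histogram, and maps are rendered with the device's
false-colour convention (blue = low through green and yellow to red =
high).

Raster semantics (stated explicitly because any convention would do):
pixels are unit squares centred on integer coordinates, 0-based,
row-major, origin top-left; a pixel belongs to the ROI iff its centre lies
strictly inside the polygon (even-odd rule; centres exactly on the
boundary are excluded).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from shapely import contains_xy
from shapely.geometry import Polygon as _ShapelyPolygon

from .records import HSI_PARAMETERS

PNG_SCALE = 655.35  # 16-bit code value per parameter unit: 100.0 -> 65535


@dataclass
class ParameterMap:
    """A 2D parameter grid on the 0-100 scale."""

    values: np.ndarray
    pixel_pitch: float = 0.1  # mm per pixel
    parameter: str = "sto2"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("parameter map must be a 2D grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("parameter map contains non-finite values")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 100):
            raise ValueError("parameter values must lie within [0, 100]")
        if not self.pixel_pitch > 0:
            raise ValueError("pixel pitch must be positive")
        if self.parameter not in HSI_PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class RoiPolygon:
    """An implicitly closed polygon in pixel coordinates (x, y)."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y) coordinates")
        if len(self.vertices) < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        shp = _ShapelyPolygon(self.vertices)
        if not shp.is_valid:
            raise ValueError("polygon is invalid (self-intersecting or degenerate)")

    def to_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    @property
    def area(self) -> float:
        return self.to_shapely().area

    @property
    def perimeter(self) -> float:
        return self.to_shapely().length


@dataclass
class RoiQuantification:
    mean: float
    sd: float
    n_pixels: int
    histogram: np.ndarray  # 100 bins of width 1 over [0, 100]

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "n_pixels": self.n_pixels,
            "histogram": [int(c) for c in self.histogram],
        }


def rasterize(polygon: RoiPolygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean ROI mask of the given (rows, cols) map shape.

    A pixel (row i, col j) is included iff its centre (x = j, y = i) lies
    inside the polygon; polygons partly or fully outside the map are
    clipped by construction.
    """
    rows, cols = shape
    if rows <= 0 or cols <= 0:
        raise ValueError("map shape must be positive")
    xs, ys = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    mask = contains_xy(polygon.to_shapely(), xs.ravel(), ys.ravel())
    return mask.reshape(rows, cols)


def quantify(pmap: ParameterMap, mask: np.ndarray) -> RoiQuantification:
    """ROI statistics over masked pixels: mean, SD (denominator n), histogram."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pmap.shape:
        raise ValueError("mask shape does not match the map")
    values = pmap.values[mask]
    if values.size == 0:
        raise ValueError("empty ROI mask: no pixel centres fall inside the polygon")
    histogram, _ = np.histogram(values, bins=np.arange(0.0, 101.0))
    return RoiQuantification(
        mean=float(values.mean()),
        sd=float(values.std(ddof=0)),
        n_pixels=int(values.size),
        histogram=histogram,
    )


def quantify_roi(pmap: ParameterMap, polygon: RoiPolygon) -> RoiQuantification:
    """Convenience: rasterize then quantify."""
    return quantify(pmap, rasterize(polygon, pmap.shape))


# false-colour anchors: value -> RGB, linearly interpolated between anchors
_ANCHOR_VALUES = np.array([0.0, 100.0 / 3.0, 200.0 / 3.0, 100.0])
_ANCHOR_RGB = np.array(
    [
        [0.0, 0.0, 1.0],  # blue = low
        [0.0, 1.0, 0.0],  # green
        [1.0, 1.0, 0.0],  # yellow
        [1.0, 0.0, 0.0],  # red = high
    ]
)


def render_pseudocolor(pmap: ParameterMap) -> np.ndarray:
    """False-colour RGB rendering (floats in [0, 1], shape (H, W, 3)).

    Deterministic piecewise-linear map with anchors blue at 0, green at
    100/3, yellow at 200/3 and red at 100.
    """
    v = pmap.values
    rgb = np.empty(v.shape + (3,), dtype=float)
    for c in range(3):
        rgb[..., c] = np.interp(v, _ANCHOR_VALUES, _ANCHOR_RGB[:, c])
    return rgb


# ---------------------------------------------------------------------------
# file formats


def write_map_png(pmap: ParameterMap, path) -> None:
    """16-bit grayscale PNG; code value = round(parameter * 655.35)."""
    codes = np.round(pmap.values * PNG_SCALE).astype(np.uint16)
    Image.fromarray(codes).save(Path(path), format="PNG")


def read_map_png(path, pixel_pitch: float = 0.1, parameter: str = "sto2") -> ParameterMap:
    codes = np.asarray(Image.open(Path(path)), dtype=np.uint16)
    return ParameterMap(codes / PNG_SCALE, pixel_pitch=pixel_pitch, parameter=parameter)


def write_map_text(pmap: ParameterMap, path) -> None:
    np.savetxt(Path(path), pmap.values, fmt="%.6f")


def read_map_text(path, pixel_pitch: float = 0.1, parameter: str = "sto2") -> ParameterMap:
    return ParameterMap(
        np.atleast_2d(np.loadtxt(Path(path))), pixel_pitch=pixel_pitch, parameter=parameter
    )


def polygon_to_geojson(polygon: RoiPolygon) -> dict:
    ring = polygon.vertices.tolist()
    if ring[0] != ring[-1]:
        ring = ring + [ring[0]]
    return {"type": "Polygon", "coordinates": [ring]}


def polygon_from_geojson(obj: dict) -> RoiPolygon:
    if obj.get("type") != "Polygon":
        raise ValueError("expected a GeoJSON Polygon")
    ring = obj["coordinates"][0]
    if len(ring) > 1 and ring[0] == ring[-1]:
        ring = ring[:-1]
    return RoiPolygon(np.asarray(ring, dtype=float))


def read_polygon(path) -> RoiPolygon:
    with open(path, "r", encoding="utf-8") as fh:
        return polygon_from_geojson(json.load(fh))


def write_polygon(polygon: RoiPolygon, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(polygon_to_geojson(polygon), fh)
        fh.write("\n")
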
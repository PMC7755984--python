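"""Raster/vector I/O and the shared grid conventions used across the pipeline.

Conventions
-----------
* Pixel coordinates are 0-based ``(row, col)`` with row 0 at the top.
* The geotransform follows the north-up GeoTIFF convention: ``yres`` is
  negative, the raster origin is the *top-left corner* of pixel (0, 0).
* Conversions use pixel centers: the map coordinate of pixel (r, c) is
  ``(origin_x + (c + 0.5) * xres, origin_y + (r + 0.5) * yres)``.
* Rasterization is pixel-center-inside (no "all touched" smearing), applied
  identically to AOI, prediction and truth masks so evaluation is
  self-consistent.
* The tool never reprojects: CRS mismatches between layers are hard errors.

Rasters are GeoTIFFs handled through :mod:`tifffile`; georeferencing is carried
by the standard GeoTIFF tags (ModelPixelScale, ModelTiepoint and a minimal
GeoKeyDirectory holding the EPSG code). Vector layers are GeoJSON handled with
:mod:`shapely`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import Polygon, mapping, shape
from shapely.geometry.polygon import orient

logger = logging.getLogger(__name__)

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
# GeoTIFF geo-keys
_GT_MODEL_TYPE = 1024
_GEOGRAPHIC_TYPE = 2048
_PROJECTED_CS_TYPE = 3072


class CRSMismatchError(ValueError):
    """Layers are in different coordinate reference systems.

    The pipeline never reprojects (silent reprojection corrupts the pixel-area
    assumptions the area filter relies on); reproject the offending layer with
    a GIS tool and re-run.
    """


@dataclass(frozen=True)
class GeoTransform:
    """North-up affine map from pixel indices to map coordinates."""

    origin_x: float
    origin_y: float
    xres: float
    yres: float

    def __post_init__(self) -> None:
        if self.xres == 0 or self.yres == 0:
            raise ValueError("pixel size must be non-zero in both directions")

    @property
    def pixel_area_m2(self) -> float:
        return abs(self.xres * self.yres)

    def pix_to_map(self, rows, cols):
        """Map coordinates of pixel centers ``(rows, cols)``."""
        rows = np.asarray(rows, dtype=float)
        cols = np.asarray(cols, dtype=float)
        x = self.origin_x + (cols + 0.5) * self.xres
        y = self.origin_y + (rows + 0.5) * self.yres
        return x, y

    def map_to_pix(self, x, y):
        """Pixel indices (row, col) containing map points ``(x, y)``."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        cols = np.floor((x - self.origin_x) / self.xres).astype(int)
        rows = np.floor((y - self.origin_y) / self.yres).astype(int)
        return rows, cols

    def corner_to_map(self, rows, cols):
        """Map coordinates of pixel *corners* (integer pixel coordinates)."""
        rows = np.asarray(rows, dtype=float)
        cols = np.asarray(cols, dtype=float)
        return (self.origin_x + cols * self.xres, self.origin_y + rows * self.yres)


@dataclass
class FieldImage:
    """A georeferenced raster: optical orthomosaic (possibly multi-band) or DSM.

    ``pixels`` is ``(rows, cols)`` or ``(rows, cols, bands)``; all bands share
    one grid and geotransform.
    """

    pixels: np.ndarray
    transform: GeoTransform
    crs: str | None = None
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be 2-D or 3-D (rows, cols[, bands])")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("raster must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def n_bands(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    @property
    def pixel_area_m2(self) -> float:
        return self.transform.pixel_area_m2

    def valid_mask(self) -> np.ndarray:
        """Boolean raster of pixels that are not nodata (any band valid)."""
        if self.nodata is None:
            return np.ones(self.shape, dtype=bool)
        px = self.pixels if self.pixels.ndim == 3 else self.pixels[..., None]
        return ~np.all(px == self.nodata, axis=-1)


@dataclass
class FieldMask:
    """Boolean AOI raster aligned to a :class:`FieldImage` grid."""

    bits: np.ndarray
    source_polygon: Polygon | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.bits.any():
            raise ValueError("AOI mask is empty: polygon does not cover any pixel center")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bits.shape


@dataclass
class PlotSegment:
    """One candidate crop-plot polygon in map coordinates."""

    id: int
    polygon: Polygon
    area_m2: float
    provenance: str = "hough"  # hough | acwe | otsu
    crs: str | None = None

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or self.polygon.is_empty:
            raise ValueError(f"segment {self.id}: polygon is invalid or empty")
        if self.area_m2 <= 0:
            raise ValueError(f"segment {self.id}: area must be positive")
        if abs(self.polygon.area - self.area_m2) > 1e-6 * max(self.area_m2, 1.0):
            raise ValueError(
                f"segment {self.id}: recorded area {self.area_m2} disagrees with "
                f"geometric area {self.polygon.area}"
            )


# ---------------------------------------------------------------------------
# raster I/O


def _geokeys_from_crs(crs: str | None) -> list[int] | None:
    if crs is None:
        return None
    try:
        authority, code = crs.split(":")
        code = int(code)
    except ValueError:
        return None
    if authority.upper() != "EPSG":
        return None
    # geographic CRS codes live in 4000-4999; everything else goes in the
    # projected key. Minimal but round-trips the codes this tool emits.
    if 4000 <= code < 5000:
        keys = [(_GT_MODEL_TYPE, 0, 1, 2), (_GEOGRAPHIC_TYPE, 0, 1, code)]
    else:
        keys = [(_GT_MODEL_TYPE, 0, 1, 1), (_PROJECTED_CS_TYPE, 0, 1, code)]
    directory = [1, 1, 0, len(keys)]
    for k in keys:
        directory.extend(k)
    return directory


def _crs_from_geokeys(directory: Sequence[int]) -> str | None:
    vals = list(directory)
    nkeys = vals[3] if len(vals) >= 4 else 0
    crs = None
    for i in range(nkeys):
        key_id, _loc, _count, value = vals[4 + 4 * i : 8 + 4 * i]
        if key_id in (_PROJECTED_CS_TYPE, _GEOGRAPHIC_TYPE) and value not in (0, 32767):
            crs = f"EPSG:{value}"
    return crs


def write_raster(image: FieldImage, path: str | Path) -> Path:
    """Write a :class:`FieldImage` as a GeoTIFF."""
    path = Path(path)
    gt = image.transform
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (abs(gt.xres), abs(gt.yres), 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, gt.origin_x, gt.origin_y, 0.0)),
    ]
    geokeys = _geokeys_from_crs(image.crs)
    if geokeys is not None:
        extratags.append((_GEO_KEY_DIRECTORY, "H", len(geokeys), tuple(geokeys)))
    data = image.pixels
    photometric = "rgb" if (data.ndim == 3 and data.shape[2] == 3) else "minisblack"
    tifffile.imwrite(path, data, photometric=photometric, extratags=extratags)
    return path


def read_raster(path: str | Path) -> FieldImage:
    """Read a GeoTIFF into a :class:`FieldImage`.

    The geotransform is required (the pipeline needs the pixel size for the
    area filter); a raster with no ModelPixelScale/ModelTiepoint tags is
    rejected with an error naming the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = tif.asarray()
            tags = {tag.code: tag.value for tag in page.tags}
    except Exception as exc:  # pragma: no cover - corrupt input
        raise IOError(f"could not read raster {path}: {exc}") from exc
    if _MODEL_PIXEL_SCALE not in tags or _MODEL_TIEPOINT not in tags:
        raise ValueError(
            f"raster {path} has no geotransform (missing GeoTIFF ModelPixelScale/"
            "ModelTiepoint tags); pixel size is required for area filtering"
        )
    sx, sy = tags[_MODEL_PIXEL_SCALE][:2]
    tie = tags[_MODEL_TIEPOINT]
    # tiepoint: raster (i, j, k) -> model (x, y, z); assume tie at pixel (0,0)
    origin_x = float(tie[3]) - float(tie[0]) * sx
    origin_y = float(tie[4]) + float(tie[1]) * sy
    transform = GeoTransform(origin_x, origin_y, float(sx), -float(sy))
    crs = None
    if _GEO_KEY_DIRECTORY in tags:
        crs = _crs_from_geokeys(tags[_GEO_KEY_DIRECTORY])
    nodata = None
    if 42113 in tags:  # GDAL_NODATA, stored as ASCII
        try:
            nodata = float(tags[42113])
        except (TypeError, ValueError):
            nodata = None
    if data.ndim == 3 and data.shape[0] < min(data.shape[1], data.shape[2]):
        # planar (bands, rows, cols) -> (rows, cols, bands)
        data = np.moveaxis(data, 0, -1)
    return FieldImage(pixels=data, transform=transform, crs=crs, nodata=nodata)


# ---------------------------------------------------------------------------
# grayscale and masking


def to_grayscale(image: FieldImage, method: str = "luminance") -> FieldImage:
    """Collapse a multi-band image to one band; single-band inputs pass through.

    ``method`` is ``"mean"``, ``"luminance"`` (Rec. 601 weights, falls back to
    mean when the image is not 3-band) or ``"band:k"`` for a 0-based band index.
    """
    if image.pixels.ndim == 2:
        return image
    px = image.pixels.astype(float)
    if method.startswith("band:"):
        k = int(method.split(":", 1)[1])
        if not 0 <= k < image.n_bands:
            raise ValueError(f"band index {k} out of range for {image.n_bands}-band image")
        gray = px[..., k]
    elif method == "mean":
        gray = px.mean(axis=-1)
    elif method == "luminance":
        if image.n_bands == 3:
            gray = px[..., 0] * 0.299 + px[..., 1] * 0.587 + px[..., 2] * 0.114
        else:
            gray = px.mean(axis=-1)
    else:
        raise ValueError(f"unknown grayscale method {method!r}")
    return FieldImage(gray, image.transform, image.crs, image.nodata)


def rasterize_polygons(
    polygons: Iterable[Polygon], image_shape: tuple[int, int], transform: GeoTransform
) -> np.ndarray:
    """Boolean raster, true where a pixel center lies strictly inside any polygon."""
    rows, cols = image_shape
    out = np.zeros((rows, cols), dtype=bool)
    for poly in polygons:
        minx, miny, maxx, maxy = poly.bounds
        # candidate pixel window from the polygon bounds
        r0, c0 = transform.map_to_pix(minx, maxy)
        r1, c1 = transform.map_to_pix(maxx, miny)
        r0, r1 = sorted((int(r0), int(r1)))
        c0, c1 = sorted((int(c0), int(c1)))
        r0, c0 = max(r0 - 1, 0), max(c0 - 1, 0)
        r1, c1 = min(r1 + 1, rows - 1), min(c1 + 1, cols - 1)
        if r1 < r0 or c1 < c0:
            continue
        rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
        x, y = transform.pix_to_map(rr.ravel(), cc.ravel())
        inside = shapely.contains_xy(poly, x, y).reshape(rr.shape)
        out[r0 : r1 + 1, c0 : c1 + 1] |= inside
    return out


def check_crs(a: str | None, b: str | None, what: str = "layers") -> None:
    """Hard-fail on CRS disagreement; missing CRS on either side is tolerated."""
    if a is not None and b is not None and a != b:
        raise CRSMismatchError(
            f"{what} are in different CRS ({a} vs {b}); reproject one of them "
            "with a GIS tool — this tool never reprojects"
        )


def rasterize_aoi(polygon: Polygon, image: FieldImage, crs: str | None = None) -> FieldMask:
    """Rasterize the field AOI polygon onto the image grid (pixel-center rule).

    nodata pixels are excluded from the mask, so they are outside the AOI
    everywhere downstream.
    """
    check_crs(crs, image.crs, "AOI polygon and raster")
    rows, cols = image.shape
    minx = image.transform.origin_x
    maxy = image.transform.origin_y
    maxx = minx + cols * image.transform.xres
    miny = maxy + rows * image.transform.yres
    footprint = shapely.box(min(minx, maxx), min(miny, maxy), max(minx, maxx), max(miny, maxy))
    if not polygon.intersects(footprint):
        raise ValueError("AOI polygon does not intersect the raster footprint")
    bits = rasterize_polygons([polygon], image.shape, image.transform)
    bits &= image.valid_mask()
    return FieldMask(bits=bits, source_polygon=polygon)


# ---------------------------------------------------------------------------
# vector I/O


def _round_coords(geom: Polygon, ndigits: int = 9) -> Polygon:
    return shapely.set_precision(geom, 10.0 ** (-ndigits), mode="pointwise")


def segments_to_geojson(segments: Sequence[PlotSegment], crs: str | None = None) -> dict:
    """Canonical GeoJSON FeatureCollection for a segment list.

    Features are sorted by id and exterior rings oriented counter-clockwise so
    repeated writes of the same segments are byte-identical.
    """
    feats = []
    for seg in sorted(segments, key=lambda s: s.id):
        geom = orient(_round_coords(seg.polygon))
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {
                    "id": seg.id,
                    "area_m2": round(seg.area_m2, 6),
                    "provenance": seg.provenance,
                },
            }
        )
    fc: dict = {"type": "FeatureCollection", "features": feats}
    if crs is None and segments:
        crs = segments[0].crs
    if crs is not None:
        # legacy named-CRS member; widely understood by GIS software
        fc["crs"] = {"type": "name", "properties": {"name": f"urn:ogc:def:crs:{crs}"}}
    return fc


def write_segments(
    segments: Sequence[PlotSegment], path: str | Path, format: str = "GeoJSON"
) -> Path:
    """Write plot segments as a vector layer (GeoJSON)."""
    if format.lower() not in ("geojson",):
        raise NotImplementedError(
            f"format {format!r} is not supported; this build writes GeoJSON only"
        )
    if not segments:
        warnings.warn("writing an empty segment layer", stacklevel=2)
    crss = {s.crs for s in segments if s.crs is not None}
    if len(crss) > 1:
        raise CRSMismatchError(f"segments carry multiple CRS: {sorted(crss)}")
    path = Path(path)
    fc = segments_to_geojson(segments)
    path.write_text(json.dumps(fc, sort_keys=True, separators=(",", ":")) + "\n")
    return path


def write_features(
    geoms_props: Sequence[tuple], path: str | Path, crs: str | None = None
) -> Path:
    """Write ``(geometry, properties)`` pairs as a GeoJSON FeatureCollection."""
    feats = [
        {"type": "Feature", "geometry": mapping(_round_coords(g)), "properties": p}
        for g, p in geoms_props
    ]
    fc: dict = {"type": "FeatureCollection", "features": feats}
    if crs is not None:
        fc["crs"] = {"type": "name", "properties": {"name": f"urn:ogc:def:crs:{crs}"}}
    path = Path(path)
    path.write_text(json.dumps(fc, sort_keys=True, separators=(",", ":")) + "\n")
    return path


def _parse_geojson_crs(fc: dict) -> str | None:
    crs = fc.get("crs")
    if not crs:
        return None
    name = crs.get("properties", {}).get("name", "")
    if "EPSG" in name.upper():
        code = name.rsplit(":", 1)[-1]
        return f"EPSG:{code}"
    return None


def read_polygons(path: str | Path) -> tuple[list[Polygon], str | None]:
    """Read polygons from a GeoJSON file (Feature/FeatureCollection/geometry)."""
    path = Path(path)
    obj = json.loads(path.read_text())
    crs = None
    if obj.get("type") == "FeatureCollection":
        crs = _parse_geojson_crs(obj)
        geoms = [shape(f["geometry"]) for f in obj["features"]]
    elif obj.get("type") == "Feature":
        geoms = [shape(obj["geometry"])]
    else:
        geoms = [shape(obj)]
    polys: list[Polygon] = []
    for g in geoms:
        if g.geom_type == "Polygon":
            polys.append(g)
        elif g.geom_type == "MultiPolygon":
            polys.extend(g.geoms)
    return polys, crs


def read_segments(path: str | Path) -> list[PlotSegment]:
    """Read a segment layer written by :func:`write_segments`."""
    path = Path(path)
    obj = json.loads(path.read_text())
    crs = _parse_geojson_crs(obj)
    segments = []
    for i, feat in enumerate(obj.get("features", [])):
        geom = shape(feat["geometry"])
        props = feat.get("properties", {}) or {}
        area = props.get("area_m2", geom.area)
        segments.append(
            PlotSegment(
                id=int(props.get("id", i + 1)),
                polygon=geom,
                area_m2=float(area),
                provenance=props.get("provenance", "hough"),
                crs=crs,
            )
        )
    return segments
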
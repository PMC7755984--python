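"""Exact raster-to-vector tracing of labeled pixel patches.

Polygons follow pixel boundaries exactly (no marching-squares corner cutting),
so a patch's geometric area in pixel units equals its pixel count.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon
from shapely.ops import polygonize as shapely_polygonize
from shapely.ops import unary_union

from .geo_io import GeoTransform


def _boundary_segments(bits: np.ndarray, r0: int, c0: int) -> list[LineString]:
    """Unit segments along the pixel boundary of a boolean patch.

    Coordinates are pixel-corner (x = col, y = row), offset by (c0, r0).
    """
    padded = np.pad(bits, 1, mode="constant")
    segs: list[LineString] = []
    rr, cc = np.nonzero(bits)
    rr = rr + 1
    cc = cc + 1
    for name, (dr, dc) in {
        "top": (-1, 0),
        "bottom": (1, 0),
        "left": (0, -1),
        "right": (0, 1),
    }.items():
        exposed = ~padded[rr + dr, cc + dc]
        for r, c in zip(rr[exposed] - 1, cc[exposed] - 1):
            x, y = int(c) + c0, int(r) + r0
            if name == "top":
                segs.append(LineString([(x, y), (x + 1, y)]))
            elif name == "bottom":
                segs.append(LineString([(x, y + 1), (x + 1, y + 1)]))
            elif name == "left":
                segs.append(LineString([(x, y), (x, y + 1)]))
            else:
                segs.append(LineString([(x + 1, y), (x + 1, y + 1)]))
    return segs


def label_polygon_pixels(bits: np.ndarray, r0: int = 0, c0: int = 0) -> Polygon:
    """Exact pixel-boundary polygon of one patch, in pixel-corner coordinates.

    Boundary unit segments are assembled into faces; a face belongs to the
    patch when its representative point falls on a true pixel. If that
    bookkeeping cannot reproduce the pixel count (possible with exotic hole
    arrangements), the exact union of per-pixel squares is used instead.
    """
    bits = np.asarray(bits, dtype=bool)
    count = int(bits.sum())
    if count == 0:
        raise ValueError("cannot polygonize an empty patch")
    faces = list(shapely_polygonize(_boundary_segments(bits, r0, c0)))
    true_faces, false_faces = [], []
    for f in faces:
        p = f.representative_point()
        r = int(np.floor(p.y)) - r0
        c = int(np.floor(p.x)) - c0
        inside = 0 <= r < bits.shape[0] and 0 <= c < bits.shape[1] and bits[r, c]
        (true_faces if inside else false_faces).append(f)
    poly = unary_union(true_faces)
    if false_faces:
        poly = poly.difference(unary_union(false_faces))
    if abs(poly.area - count) > 1e-6:
        rr, cc = np.nonzero(bits)
        boxes = shapely.box(cc + c0, rr + r0, cc + c0 + 1.0, rr + r0 + 1.0)
        poly = shapely.coverage_union_all(boxes)
    if poly.geom_type == "MultiPolygon":
        poly = max(poly.geoms, key=lambda g: g.area)
    return poly.simplify(0)


def mask_to_map_polygon(
    bits: np.ndarray, transform: GeoTransform, r0: int = 0, c0: int = 0
) -> Polygon:
    """Pixel patch -> map-coordinate polygon along exact pixel boundaries."""
    pix_poly = label_polygon_pixels(bits, r0=r0, c0=c0)

    def to_map(coords: np.ndarray) -> np.ndarray:
        x, y = transform.corner_to_map(coords[:, 1], coords[:, 0])
        return np.column_stack([x, y])

    return shapely.transform(pix_poly, to_map)
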
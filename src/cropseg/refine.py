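"""Optional per-segment boundary refinement: morphological active contours
(Chan-Vese without edges, the erosion/dilation variant) or Otsu foreground
thresholding.

Refinement is per segment within a padded bounding box, not global, so
neighbouring plots cannot capture each other's pixels; any overlaps left after
refinement are resolved by assigning contested pixels to the segment with the
nearer centroid. A guarded fallback returns the input segment unchanged
whenever refinement degenerates (empty result, or area growth beyond 4x).

The pipeline found no consistent accuracy gain from either refiner on typical
fields, so refinement ships off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.segmentation import morphological_chan_vese

from .geo_io import FieldImage, PlotSegment, rasterize_polygons
from .vectorize import mask_to_map_polygon

logger = logging.getLogger(__name__)

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class RefineParams:
    method: str = "acwe"  # acwe | otsu
    iterations: int = 50
    smoothing: int = 1
    lambda1: float = 1.0
    lambda2: float = 1.0
    dilation_px: int = 10

    def __post_init__(self) -> None:
        if self.method not in ("acwe", "otsu"):
            raise ValueError("method must be 'acwe' or 'otsu'")
        if self.iterations < 1 or self.smoothing < 0 or self.dilation_px < 0:
            raise ValueError("iterations >= 1, smoothing >= 0, dilation_px >= 0 required")
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("lambda1 and lambda2 must be positive")


def chan_vese_energy(
    window: np.ndarray, mask: np.ndarray, lambda1: float = 1.0, lambda2: float = 1.0
) -> float:
    """Piecewise-constant Chan-Vese energy (region terms) of a partition."""
    window = np.asarray(window, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    inside = window[mask]
    outside = window[~mask]
    e = 0.0
    if inside.size:
        e += lambda1 * float(((inside - inside.mean()) ** 2).sum())
    if outside.size:
        e += lambda2 * float(((outside - outside.mean()) ** 2).sum())
    return e


def _segment_window(
    image: FieldImage, segment: PlotSegment, pad_px: int
) -> tuple[slice, slice, np.ndarray]:
    """Padded bbox window of the segment plus its rasterized footprint."""
    rows, cols = image.shape
    minx, miny, maxx, maxy = segment.polygon.bounds
    r0, c0 = image.transform.map_to_pix(minx, maxy)
    r1, c1 = image.transform.map_to_pix(maxx, miny)
    r0, r1 = sorted((int(r0), int(r1)))
    c0, c1 = sorted((int(c0), int(c1)))
    r0 = max(r0 - pad_px, 0)
    c0 = max(c0 - pad_px, 0)
    r1 = min(r1 + pad_px, rows - 1)
    c1 = min(c1 + pad_px, cols - 1)
    if r1 < r0 or c1 < c0:
        raise ValueError(f"segment {segment.id} does not intersect the image grid")
    rs, cs = slice(r0, r1 + 1), slice(c0, c1 + 1)
    footprint = rasterize_polygons([segment.polygon], image.shape, image.transform)[rs, cs]
    return rs, cs, footprint


def _largest_overlapping_component(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    labels, n = ndi.label(mask, structure=_FOUR_CONN)
    if n == 0:
        return np.zeros_like(mask)
    overlaps = ndi.sum_labels(footprint.astype(int), labels, index=np.arange(1, n + 1))
    if overlaps.max() > 0:
        best = int(np.argmax(overlaps)) + 1
    else:
        sizes = np.bincount(labels.ravel())[1:]
        best = int(np.argmax(sizes)) + 1
    return labels == best


def _refined_mask(
    image: FieldImage, segment: PlotSegment, params: RefineParams
) -> tuple[slice, slice, np.ndarray, np.ndarray]:
    """Run the configured refiner; returns window slices, refined and input masks."""
    if image.pixels.ndim != 2:
        raise ValueError("refinement needs a single-band image; use to_grayscale")
    rs, cs, footprint = _segment_window(image, segment, params.dilation_px)
    window = np.asarray(image.pixels[rs, cs], dtype=float)
    if params.method == "acwe":
        if footprint.sum() == 0 or np.all(window == window.flat[0]):
            return rs, cs, footprint, footprint
        refined = morphological_chan_vese(
            window,
            num_iter=params.iterations,
            init_level_set=footprint,
            smoothing=params.smoothing,
            lambda1=params.lambda1,
            lambda2=params.lambda2,
        ).astype(bool)
        refined = _largest_overlapping_component(refined, footprint)
    else:
        if np.all(window == window.flat[0]):
            return rs, cs, footprint, footprint
        thresh = threshold_otsu(window)
        refined = _largest_overlapping_component(window > thresh, footprint)
    # guarded fallback: never return an empty or exploded segment
    if refined.sum() == 0 or refined.sum() > 4 * max(footprint.sum(), 1):
        logger.warning("segment %d: refinement degenerated, keeping input", segment.id)
        return rs, cs, footprint, footprint
    return rs, cs, refined, footprint


def _mask_to_segment(
    image: FieldImage, segment: PlotSegment, rs: slice, cs: slice, bits: np.ndarray, method: str
) -> PlotSegment:
    if bits.sum() == 0:
        return segment
    poly = mask_to_map_polygon(bits, image.transform, r0=rs.start, c0=cs.start)
    return PlotSegment(
        id=segment.id,
        polygon=poly,
        area_m2=int(bits.sum()) * image.pixel_area_m2,
        provenance=method,
        crs=segment.crs,
    )


def acwe_refine(image: FieldImage, segment: PlotSegment, params: RefineParams) -> PlotSegment:
    """Morphological Chan-Vese evolution initialized from the segment footprint."""
    params = params if params.method == "acwe" else RefineParams(**{**params.__dict__, "method": "acwe"})
    rs, cs, refined, footprint = _refined_mask(image, segment, params)
    if refined is footprint:
        return segment
    return _mask_to_segment(image, segment, rs, cs, refined, "acwe")


def otsu_refine(image: FieldImage, segment: PlotSegment, params: RefineParams) -> PlotSegment:
    """Largest Otsu-foreground component overlapping the segment footprint."""
    params = params if params.method == "otsu" else RefineParams(**{**params.__dict__, "method": "otsu"})
    rs, cs, refined, footprint = _refined_mask(image, segment, params)
    if refined is footprint:
        return segment
    return _mask_to_segment(image, segment, rs, cs, refined, "otsu")


def refine_segments(
    image: FieldImage, segments: list[PlotSegment], params: RefineParams
) -> list[PlotSegment]:
    """Refine every segment, then restore disjointness.

    Contested pixels (claimed by more than one refined segment) go to the
    segment whose centroid is nearest.
    """
    if not segments:
        return []
    rows, cols = image.shape
    claims: list[tuple[PlotSegment, slice, slice, np.ndarray]] = []
    for seg in segments:
        rs, cs, refined, _ = _refined_mask(image, seg, params)
        claims.append((seg, rs, cs, refined))

    count = np.zeros((rows, cols), dtype=np.int16)
    for _, rs, cs, bits in claims:
        count[rs, cs] += bits
    contested = count > 1

    if contested.any():
        rr, cc = np.nonzero(contested)
        centroids = []
        claimed = np.zeros((rr.size, len(claims)), dtype=bool)
        for i, (_, rs, cs, bits) in enumerate(claims):
            r_idx, c_idx = np.nonzero(bits)
            if r_idx.size == 0:
                centroids.append((np.inf, np.inf))
                continue
            centroids.append((r_idx.mean() + rs.start, c_idx.mean() + cs.start))
            rw = rr - rs.start
            cw = cc - cs.start
            inw = (rw >= 0) & (rw < bits.shape[0]) & (cw >= 0) & (cw < bits.shape[1])
            claimed[inw, i] = bits[rw[inw], cw[inw]]
        centroids = np.asarray(centroids)
        d2 = (rr[:, None] - centroids[None, :, 0]) ** 2 + (cc[:, None] - centroids[None, :, 1]) ** 2
        d2[~claimed] = np.inf
        winner = np.argmin(d2, axis=1)

    out = []
    for i, (seg, rs, cs, bits) in enumerate(claims):
        bits = bits.copy()
        win_contested = contested[rs, cs] & bits
        if win_contested.any():
            bits[win_contested] = False
            if contested.any():
                mine = winner == i
                r_keep = rr[mine] - rs.start
                c_keep = cc[mine] - cs.start
                ok = (r_keep >= 0) & (r_keep < bits.shape[0]) & (c_keep >= 0) & (c_keep < bits.shape[1])
                bits[r_keep[ok], c_keep[ok]] = True
        out.append(_mask_to_segment(image, seg, rs, cs, bits, params.method))
    return out
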
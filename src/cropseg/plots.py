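"""Line raster to plot segments: labeling, area filtering, polygonization and
the end-to-end segmentation pipeline.

The merged line raster divides the AOI interior into cells. Cells are labeled
with 4-connectivity so that 1 px diagonal line crossings still separate
neighbours, filtered by area in m² (areas always come from the geotransform,
never pixel counts alone, so presets transfer across resolutions), and traced
into map-coordinate polygons along exact pixel boundaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Polygon

from . import refine as refine_mod
from .edges import CannyParams, EdgeMap, PCParams, canny_edges, dual_axis_edges, pc_edges
from .geo_io import (
    FieldImage,
    FieldMask,
    GeoTransform,
    PlotSegment,
    rasterize_aoi,
    to_grayscale,
)
from .hough import AxisOrientation, LineSet, constrained_hough, estimate_axes, render_lines
from .refine import RefineParams
from .vectorize import mask_to_map_polygon

logger = logging.getLogger(__name__)


@dataclass
class SegmentLabels:
    """Labeled segment raster: 0 = background/lines/outside mask, k >= 1 = segment."""

    labels: np.ndarray
    pixel_area_m2: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.pixel_area_m2 <= 0:
            raise ValueError("pixel_area_m2 must be positive")

    @property
    def n_segments(self) -> int:
        return int(self.labels.max())

    def pixel_counts(self) -> np.ndarray:
        """Pixel count per label, index 0 = background."""
        return np.bincount(self.labels.ravel(), minlength=self.n_segments + 1)

    def areas_m2(self) -> np.ndarray:
        return self.pixel_counts()[1:] * self.pixel_area_m2


_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def build_segments(
    line_raster: np.ndarray, mask: FieldMask, pixel_area_m2: float
) -> SegmentLabels:
    """4-connected components of in-mask pixels not covered by any line."""
    line_raster = np.asarray(line_raster, dtype=bool)
    if line_raster.shape != mask.shape:
        raise ValueError("line raster and mask are not aligned")
    interior = mask.bits & ~line_raster
    labels, n = ndi.label(interior, structure=_FOUR_CONN)
    if n == 0:
        warnings.warn("no enclosed areas: line raster covers the whole AOI interior")
    return SegmentLabels(labels=labels, pixel_area_m2=pixel_area_m2)


def filter_by_area(
    segs: SegmentLabels, min_area_m2: float, max_area_m2: Optional[float] = None
) -> SegmentLabels:
    """Discard segments outside [min_area_m2, max_area_m2]; renumber from 1."""
    if min_area_m2 <= 0:
        raise ValueError("min_area_m2 must be positive")
    if max_area_m2 is not None and max_area_m2 <= min_area_m2:
        raise ValueError("max_area_m2 must exceed min_area_m2")
    counts = segs.pixel_counts()
    areas = counts * segs.pixel_area_m2
    keep = areas >= min_area_m2
    if max_area_m2 is not None:
        keep &= areas <= max_area_m2
    keep[0] = False
    # consecutive relabeling, preserving original label order
    remap = np.zeros(len(counts), dtype=segs.labels.dtype)
    remap[keep] = np.arange(1, int(keep.sum()) + 1)
    return SegmentLabels(labels=remap[segs.labels], pixel_area_m2=segs.pixel_area_m2)


# ---------------------------------------------------------------------------
# polygonization


def polygonize(
    segs: SegmentLabels, transform: GeoTransform, crs: str | None = None
) -> list[PlotSegment]:
    """One map-coordinate polygon per label, tracing exterior pixel boundaries."""
    out: list[PlotSegment] = []
    if segs.n_segments == 0:
        return out
    slices = ndi.find_objects(segs.labels)
    for k, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        patch = segs.labels[sl] == k
        map_poly = mask_to_map_polygon(patch, transform, r0=sl[0].start, c0=sl[1].start)
        count = int(patch.sum())
        out.append(
            PlotSegment(
                id=k,
                polygon=map_poly,
                area_m2=count * segs.pixel_area_m2,
                provenance="hough",
                crs=crs,
            )
        )
    return out


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class HoughConfig:
    tolerance_deg: float = 5.0
    theta_step_deg: float = 0.5
    peak_frac: float = 0.25
    min_r_sep_px: float = 3.0
    min_theta_sep_deg: float = 2.0


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs beyond the input rasters."""

    edge_algorithm: str = "CN"  # CN | PC
    canny: CannyParams = dc_field(default_factory=CannyParams)
    pc: PCParams = dc_field(default_factory=PCParams)
    dual_axis: bool = False
    canny_minor: Optional[CannyParams] = None
    pc_minor: Optional[PCParams] = None
    min_area_m2: float = 3.5
    max_area_m2: Optional[float] = None
    hough: HoughConfig = dc_field(default_factory=HoughConfig)
    refine: str = "none"  # none | acwe | otsu
    refine_params: Optional[RefineParams] = None
    line_width_px: float = 1.0
    grayscale: str = "luminance"

    def __post_init__(self) -> None:
        if self.edge_algorithm not in ("CN", "PC"):
            raise ValueError("edge_algorithm must be 'CN' or 'PC'")
        if self.max_area_m2 is not None and not 0 < self.min_area_m2 < self.max_area_m2:
            raise ValueError("need 0 < min_area_m2 < max_area_m2")
        if self.refine not in ("none", "acwe", "otsu"):
            raise ValueError("refine must be none, acwe or otsu")


@dataclass
class Diagnostics:
    """Intermediate products retained for inspection."""

    mask: FieldMask | None = None
    axes: AxisOrientation | None = None
    edges_major: EdgeMap | None = None
    edges_minor: EdgeMap | None = None
    lines_major: LineSet | None = None
    lines_minor: LineSet | None = None
    line_raster: np.ndarray | None = None
    labels: SegmentLabels | None = None


class StageError(RuntimeError):
    """Pipeline failure wrapped with the name of the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def segment_plots(
    image: FieldImage, aoi: Polygon, config: PipelineConfig | None = None
) -> tuple[list[PlotSegment], Diagnostics]:
    """Run the full chain: mask, grayscale, edges, per-axis Hough, merge,
    label, area-filter, optional refinement, polygonize."""
    config = config or PipelineConfig()
    diag = Diagnostics()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - reported with stage context
            raise StageError(name, exc) from exc

    mask = stage("mask", rasterize_aoi, aoi, image)
    diag.mask = mask
    gray = stage("grayscale", to_grayscale, image, config.grayscale)
    axes = stage("axes", estimate_axes, mask)
    diag.axes = axes

    def make_edges():
        if config.dual_axis:
            pmaj = config.canny if config.edge_algorithm == "CN" else config.pc
            if config.edge_algorithm == "CN":
                pmin = config.canny_minor or config.canny
            else:
                pmin = config.pc_minor or config.pc
            return dual_axis_edges(gray, pmaj, pmin, mask)
        if config.edge_algorithm == "CN":
            em = canny_edges(gray, config.canny, mask)
        else:
            em = pc_edges(gray, config.pc, mask)
        return em, em

    em_major, em_minor = stage("edges", make_edges)
    diag.edges_major, diag.edges_minor = em_major, em_minor

    hc = config.hough
    lines_major = stage(
        "hough-major",
        constrained_hough,
        em_major,
        axes,
        "major",
        hc.tolerance_deg,
        hc.theta_step_deg,
        hc.peak_frac,
        hc.min_r_sep_px,
        hc.min_theta_sep_deg,
    )
    lines_minor = stage(
        "hough-minor",
        constrained_hough,
        em_minor,
        axes,
        "minor",
        hc.tolerance_deg,
        hc.theta_step_deg,
        hc.peak_frac,
        hc.min_r_sep_px,
        hc.min_theta_sep_deg,
    )
    diag.lines_major, diag.lines_minor = lines_major, lines_minor

    line_raster = stage(
        "render", render_lines, lines_major.merged(lines_minor), image.shape, config.line_width_px
    )
    diag.line_raster = line_raster

    labels = stage("label", build_segments, line_raster, mask, image.pixel_area_m2)
    labels = stage("area-filter", filter_by_area, labels, config.min_area_m2, config.max_area_m2)
    diag.labels = labels

    segments = stage("polygonize", polygonize, labels, image.transform, image.crs)
    if config.refine != "none" and segments:
        params = config.refine_params or RefineParams(method=config.refine)
        segments = stage("refine", refine_mod.refine_segments, gray, segments, params)
    if not segments:
        warnings.warn("pipeline produced zero segments")
    return segments, diag
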
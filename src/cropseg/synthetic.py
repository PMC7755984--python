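"""Synthetic UAS field scenes with known plot-grid ground truth.

Real trial fields are grids of small rectangular crop plots separated by
narrow soil/furrow divisions (often just a plough line), flown at 20-50 m AGL
so the ground sampling distance is a few centimetres. No public imagery ships
with this package, so the generator emulates the two raster products the
pipeline consumes:

* ``optical`` — bright textured plot canopies (mean 180 DN) over dark soil
  divisions (mean 60 DN), Gaussian texture noise, an optional multiplicative
  illumination ramp (cast-shadow gradient) and a 1 px optical blur;
* ``dsm`` — raised plot plateaus (0.30 m + a smooth canopy crown) on a flat
  ground plane with centimetre-level reconstruction noise.

Every scene carries a synthetic UTM-like geotransform so all geospatial code
paths (areas in m², polygon I/O, CRS checks) are exercised, plus exact
ground-truth plot polygons and the division centrelines the line-detection
stage is expected to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, Polygon

from .geo_io import FieldImage, GeoTransform, PlotSegment

_ORIGIN_X = 440_000.0  # arbitrary UTM-like false origin
_ORIGIN_Y = 5_771_000.0
_CRS = "EPSG:32630"


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic field scene.

    Defaults describe a mid-season oat trial: a 6 x 10 grid of 1.5 m x 3.0 m
    plots (4.5 m², comfortably above the 3.5 m² plot size the area filter
    presets assume) separated by 0.10 m plough-line divisions, sampled at a
    2.5 cm ground sampling distance.
    """

    rows: int = 6
    cols: int = 10
    plot_w_m: float = 1.5
    plot_h_m: float = 3.0
    gap_m: float = 0.10
    angle_deg: float = 0.0
    pixel_m: float = 0.025
    margin_m: float = 0.8
    seed: int = 0
    mode: str = "optical"  # optical | dsm
    noise_sd: float = 8.0
    shadow_strength: float = 0.0  # multiplicative ramp amplitude, 0..1
    emergence_frac: float = 1.0

    def __post_init__(self) -> None:
        if min(self.rows, self.cols) < 1:
            raise ValueError("grid must contain at least one plot")
        for name in ("plot_w_m", "plot_h_m", "gap_m", "pixel_m", "margin_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.emergence_frac <= 1:
            raise ValueError("emergence_frac must be in (0, 1]")
        if self.mode not in ("optical", "dsm"):
            raise ValueError(f"unknown scene mode {self.mode!r}")

    @property
    def pitch_x(self) -> float:
        return self.plot_w_m + self.gap_m

    @property
    def pitch_y(self) -> float:
        return self.plot_h_m + self.gap_m

    @property
    def grid_w_m(self) -> float:
        return self.cols * self.plot_w_m + (self.cols - 1) * self.gap_m

    @property
    def grid_h_m(self) -> float:
        return self.rows * self.plot_h_m + (self.rows - 1) * self.gap_m


def _rotation(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


def _grid_to_map(spec: SceneSpec, u, v):
    """Grid-local coords (u right, v up, origin at grid lower-left) -> map."""
    R = _rotation(spec.angle_deg)
    x = _ORIGIN_X + R[0, 0] * u + R[0, 1] * v
    y = _ORIGIN_Y + R[1, 0] * u + R[1, 1] * v
    return x, y


def _map_to_grid(spec: SceneSpec, x, y):
    R = _rotation(spec.angle_deg)
    dx = x - _ORIGIN_X
    dy = y - _ORIGIN_Y
    u = R[0, 0] * dx + R[1, 0] * dy
    v = R[0, 1] * dx + R[1, 1] * dy
    return u, v


def aoi_polygon(spec: SceneSpec) -> Polygon:
    """Rotated field rectangle: the grid extent buffered by the soil margin."""
    m = spec.margin_m
    corners = [(-m, -m), (spec.grid_w_m + m, -m), (spec.grid_w_m + m, spec.grid_h_m + m), (-m, spec.grid_h_m + m)]
    pts = [_grid_to_map(spec, u, v) for u, v in corners]
    return Polygon(pts)


def truth_polygons(spec: SceneSpec) -> list[PlotSegment]:
    """Exact plot rectangles in map coordinates, row-major ids from 1."""
    out = []
    k = 0
    for i in range(spec.rows):
        for j in range(spec.cols):
            k += 1
            u0 = j * spec.pitch_x
            v0 = (spec.rows - 1 - i) * spec.pitch_y  # row 0 at the top (north)
            corners = [
                (u0, v0),
                (u0 + spec.plot_w_m, v0),
                (u0 + spec.plot_w_m, v0 + spec.plot_h_m),
                (u0, v0 + spec.plot_h_m),
            ]
            poly = Polygon([_grid_to_map(spec, u, v) for u, v in corners])
            out.append(
                PlotSegment(id=k, polygon=poly, area_m2=poly.area, provenance="hough", crs=_CRS)
            )
    return out


def gap_centerlines(spec: SceneSpec) -> list[tuple[LineString, str]]:
    """Division centrelines (and the outer grid boundary lines) in map coords.

    Returns ``(line, axis_tag)`` pairs where the tag names the grid direction
    the line runs along: ``"v"`` for lines of constant u (parallel to the plot
    columns) and ``"h"`` for lines of constant v.
    """
    lines = []
    us = [0.0] + [j * spec.pitch_x - spec.gap_m / 2 for j in range(1, spec.cols)] + [spec.grid_w_m]
    vs = [0.0] + [i * spec.pitch_y - spec.gap_m / 2 for i in range(1, spec.rows)] + [spec.grid_h_m]
    for u in us:
        p0 = _grid_to_map(spec, u, -spec.margin_m)
        p1 = _grid_to_map(spec, u, spec.grid_h_m + spec.margin_m)
        lines.append((LineString([p0, p1]), "v"))
    for v in vs:
        p0 = _grid_to_map(spec, -spec.margin_m, v)
        p1 = _grid_to_map(spec, spec.grid_w_m + spec.margin_m, v)
        lines.append((LineString([p0, p1]), "h"))
    return lines


def _scene_grid(spec: SceneSpec) -> tuple[GeoTransform, int, int]:
    aoi = aoi_polygon(spec)
    minx, miny, maxx, maxy = aoi.bounds
    pad = 2 * spec.pixel_m
    minx, miny, maxx, maxy = minx - pad, miny - pad, maxx + pad, maxy + pad
    cols = int(np.ceil((maxx - minx) / spec.pixel_m))
    rows = int(np.ceil((maxy - miny) / spec.pixel_m))
    if rows * cols > 4e7:
        raise ValueError("requested grid is too large for the raster extent")
    transform = GeoTransform(minx, maxy, spec.pixel_m, -spec.pixel_m)
    return transform, rows, cols


def make_scene(spec: SceneSpec) -> tuple[FieldImage, Polygon, list[PlotSegment]]:
    """Render a scene: ``(image, aoi_polygon, truth_segments)``.

    Deterministic under ``spec.seed``.
    """
    transform, rows, cols = _scene_grid(spec)
    rng = np.random.default_rng(spec.seed)

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x, y = transform.pix_to_map(rr, cc)
    u, v = _map_to_grid(spec, x, y)

    in_grid = (u >= 0) & (u < spec.grid_w_m) & (v >= 0) & (v < spec.grid_h_m)
    fu = np.mod(u, spec.pitch_x)
    fv = np.mod(v, spec.pitch_y)
    in_plot = in_grid & (fu < spec.plot_w_m) & (fv < spec.plot_h_m)
    if spec.emergence_frac < 1.0:
        # partial emergence: plant signal only on a random subset of canopy
        # pixels (sparse seedlings over visible soil)
        speckle = rng.random((rows, cols)) < spec.emergence_frac
        planted = in_plot & speckle
    else:
        planted = in_plot

    if spec.mode == "optical":
        img = np.full((rows, cols), 60.0)
        img[planted] = 180.0
        img += rng.normal(0.0, spec.noise_sd, size=(rows, cols))
        img = gaussian_filter(img, sigma=1.0)
        if spec.shadow_strength > 0:
            t = (cc / max(cols - 1, 1) + rr / max(rows - 1, 1)) / 2.0
            img *= 1.0 - spec.shadow_strength * t
        img = np.clip(img, 0.0, 255.0)
    else:
        img = np.zeros((rows, cols))
        # plateau + smooth canopy crown peaking mid-plot
        crown = np.zeros((rows, cols))
        with np.errstate(invalid="ignore"):
            crown_u = np.sin(np.pi * np.clip(fu / spec.plot_w_m, 0, 1))
            crown_v = np.sin(np.pi * np.clip(fv / spec.plot_h_m, 0, 1))
        crown = 0.10 * crown_u * crown_v
        img[planted] = 0.30 + crown[planted]
        img += rng.normal(0.0, 0.02, size=(rows, cols))
        img = gaussian_filter(img, sigma=1.0)

    image = FieldImage(pixels=img, transform=transform, crs=_CRS)
    return image, aoi_polygon(spec), truth_polygons(spec)


def scene_family(
    base: SceneSpec, rotations: Iterable[float], seeds: Iterable[int]
) -> list[tuple[SceneSpec, FieldImage, Polygon, list[PlotSegment]]]:
    """Cartesian product of rotations x seeds, rendered.

    Used by the acceptance suite to sweep grid orientation and noise draws.
    """
    rotations = list(rotations)
    seeds = list(seeds)
    if not rotations or not seeds:
        raise ValueError("rotations and seeds must be non-empty")
    out = []
    for rot in rotations:
        for seed in seeds:
            spec = replace(base, angle_deg=rot, seed=seed)
            image, aoi, truth = make_scene(spec)
            out.append((spec, image, aoi, truth))
    return out
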
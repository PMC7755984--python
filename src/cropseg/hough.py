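"""Axis estimation and orientation-constrained standard Hough line detection.

Plot divisions in a trial field run in two near-perpendicular directions, so
the Hough parameter space is restricted to normal angles near each field axis
rather than searched exhaustively: the two perpendicular line families are
detected separately and merged downstream.

Angle conventions (the main interoperability hazard, stated explicitly):

* All angles here are in *array* coordinates: x = col, y = row with row 0 at
  the top, measured counter-clockwise from +x toward +y, in [0, 180) degrees.
  Under a north-up geotransform an array angle ``a`` corresponds to the map
  (geographic, CCW-from-east) angle ``(-a) mod 180``.
* Lines are in Hesse normal form ``x cos(theta) + y sin(theta) = r`` with the
  origin at pixel (0, 0), ``r`` in pixels and the normal angle ``theta`` in
  [-90, 90) degrees. A line *parallel* to an axis at angle ``a`` has normal
  ``theta = a - 90 (mod 180)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from shapely.geometry import MultiPoint
from skimage.transform import hough_line

from .edges import EdgeMap
from .geo_io import FieldMask

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AxisOrientation:
    """Field major/minor axis directions, degrees in [0, 180), array convention."""

    major_deg: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "major_deg", float(np.mod(self.major_deg, 180.0)))

    @property
    def minor_deg(self) -> float:
        return float(np.mod(self.major_deg + 90.0, 180.0))

    def angle(self, axis: str) -> float:
        if axis == "major":
            return self.major_deg
        if axis == "minor":
            return self.minor_deg
        raise ValueError(f"axis must be 'major' or 'minor', got {axis!r}")


@dataclass(frozen=True)
class HoughLine:
    """One detected line in Hesse normal form (pixel units)."""

    r: float
    theta: float  # radians in [-pi/2, pi/2)
    votes: int
    axis_tag: str  # major | minor

    def distance_to(self, x, y):
        """Perpendicular distance from points (array coords) to the line."""
        return np.abs(
            np.asarray(x) * np.cos(self.theta) + np.asarray(y) * np.sin(self.theta) - self.r
        )


@dataclass
class LineSet:
    lines: list[HoughLine] = field(default_factory=list)
    tolerance_deg: float = 5.0
    theta_step_deg: float = 0.5

    def __len__(self) -> int:
        return len(self.lines)

    def __iter__(self):
        return iter(self.lines)

    def merged(self, other: "LineSet") -> "LineSet":
        return LineSet(
            lines=self.lines + other.lines,
            tolerance_deg=self.tolerance_deg,
            theta_step_deg=self.theta_step_deg,
        )


# ---------------------------------------------------------------------------


def estimate_axes(mask: FieldMask) -> AxisOrientation:
    """Field axis orientation from the AOI mask.

    The major axis is the orientation of the longer side of the mask's
    minimum-area rotated bounding rectangle (computed from the convex hull of
    the true pixel centers); the minor axis is at +90 degrees. For a square
    rectangle (tied side lengths) the first-encountered side wins, which is
    deterministic for a given mask.
    """
    rr, cc = np.nonzero(mask.bits)
    if rr.size < 3:
        raise ValueError("mask has fewer than 3 true pixels; cannot orient axes")
    hull = MultiPoint(np.column_stack([cc, rr])).convex_hull
    rect = hull.minimum_rotated_rectangle
    if rect.geom_type != "Polygon":  # degenerate: collinear pixels
        raise ValueError("mask pixels are collinear; cannot orient axes")
    coords = np.asarray(rect.exterior.coords)[:4]
    s1 = coords[1] - coords[0]
    s2 = coords[2] - coords[1]
    side = s1 if np.hypot(*s1) >= np.hypot(*s2) else s2
    major = np.rad2deg(np.arctan2(side[1], side[0]))
    return AxisOrientation(major_deg=major)


def hough_accumulator(
    edge_bits: np.ndarray, thetas_rad: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standard (non-probabilistic) Hough accumulator over the given angles.

    Returns ``(accumulator, thetas, r_bins)``; r bins are 1 px wide, spanning
    the image diagonal both ways. Votes use round-half-away binning of
    ``x cos(theta) + y sin(theta)``.
    """
    acc, thetas, dists = hough_line(edge_bits, theta=thetas_rad)
    return acc.astype(np.int64), thetas, dists


def _axis_thetas(
    axes: AxisOrientation, axis: str, tolerance_deg: float, theta_step_deg: float
) -> np.ndarray:
    """Sampled normal angles (radians) within +-tolerance of the axis window."""
    if not 0 < tolerance_deg < 45:
        raise ValueError("tolerance_deg must be in (0, 45)")
    normal = axes.angle(axis) - 90.0  # normal angle of lines parallel to the axis
    n = int(np.floor(tolerance_deg / theta_step_deg))
    offs = np.arange(-n, n + 1) * theta_step_deg
    degs = np.mod(normal + offs + 90.0, 180.0) - 90.0  # map into [-90, 90)
    return np.deg2rad(np.sort(degs))


def _center_offset(r: float, theta: float, center: tuple[float, float]) -> float:
    """Signed perpendicular offset of the line from the image center.

    ``r`` is referenced to the array origin (pixel 0,0); different (r, theta)
    bins of the same physical line have nearly identical *center* offsets,
    which makes this the right key for deduplication within an axis family
    (where all true lines are near-parallel, as in a plot grid).
    """
    cx, cy = center
    return r - (cx * np.cos(theta) + cy * np.sin(theta))


def constrained_hough(
    edges: EdgeMap,
    axes: AxisOrientation,
    axis: str,
    tolerance_deg: float = 5.0,
    theta_step_deg: float = 0.5,
    peak_frac: float = 0.25,
    min_r_sep_px: float = 3.0,
    min_theta_sep_deg: float = 2.0,
    min_votes: Optional[float] = None,
) -> LineSet:
    """Detect lines near-parallel to one field axis.

    The accumulator is computed only over normal angles within
    ``+-tolerance_deg`` of the axis normal, sampled at ``theta_step_deg``.
    Peaks with votes >= ``peak_frac`` x max — and above an absolute floor of
    ``min_votes`` (default 5% of the image diagonal, rejecting stray
    single-pixel coincidences) — are returned, deduplicated: a candidate is
    dropped when its perpendicular offset from the image center is within
    ``min_r_sep_px`` of an accepted line's (different accumulator bins of one
    physical line share the same center offset; distinct lines of one axis
    family are near-parallel and well separated), or when it is closer than
    both ``min_r_sep_px`` in r and ``min_theta_sep_deg`` in angle. Candidates
    are visited by higher votes, then smaller \\|r\\|, then smaller theta, so
    output is deterministic.
    """
    result = LineSet(tolerance_deg=tolerance_deg, theta_step_deg=theta_step_deg)
    if edges.n_edges == 0:
        logger.warning("empty edge map: no lines to detect on %s axis", axis)
        return result
    thetas = _axis_thetas(axes, axis, tolerance_deg, theta_step_deg)
    acc, thetas, dists = hough_accumulator(edges.bits, thetas)
    vmax = int(acc.max())
    h, w = edges.bits.shape
    if min_votes is None:
        min_votes = 0.05 * np.hypot(h, w)
    if vmax < min_votes:
        return result
    threshold = max(peak_frac * vmax, min_votes)
    ri, ti = np.nonzero(acc >= threshold)
    votes = acc[ri, ti]
    cand_r = dists[ri].astype(float)
    cand_t = thetas[ti]
    order = np.lexsort((cand_t, np.abs(cand_r), -votes))
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    min_theta_sep = np.deg2rad(min_theta_sep_deg)
    accepted_offsets: list[float] = []
    for idx in order:
        r, theta, v = cand_r[idx], float(cand_t[idx]), int(votes[idx])
        rc = _center_offset(r, theta, center)
        duplicate = False
        for a, rc_a in zip(result.lines, accepted_offsets):
            dtheta = abs(a.theta - theta)
            flip = dtheta > np.pi / 2  # antiparallel normals: compare -rc
            dtheta = min(dtheta, np.pi - dtheta)
            rc_b = -rc if flip else rc
            if abs(rc_a - rc_b) < min_r_sep_px:
                duplicate = True
            elif dtheta < min_theta_sep and abs(a.r - r) < min_r_sep_px:
                duplicate = True
            if duplicate:
                break
        if not duplicate:
            result.lines.append(HoughLine(r=r, theta=theta, votes=v, axis_tag=axis))
            accepted_offsets.append(rc)
    return result


def render_lines(lines: LineSet, grid_shape: tuple[int, int], width_px: float = 1.0) -> np.ndarray:
    """Draw every detected line across the full grid extent at the given width.

    A pixel is on a line when its center lies within ``width_px / 2`` of the
    line (perpendicular point-to-line distance); the output is the union over
    all lines.
    """
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    rows, cols = grid_shape
    out = np.zeros((rows, cols), dtype=bool)
    if not len(lines):
        return out
    yy, xx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    for line in lines:
        out |= line.distance_to(xx, yy) <= width_px / 2.0
    return out
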
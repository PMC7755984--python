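"""Axis estimation and constrained Hough line detection."""

import numpy as np
import pytest
import shapely
from shapely import affinity

from cropseg.edges import CannyParams, EdgeMap, canny_edges
from cropseg.geo_io import FieldMask, GeoTransform, rasterize_aoi, rasterize_polygons
from cropseg.hough import (
    AxisOrientation,
    HoughLine,
    LineSet,
    constrained_hough,
    estimate_axes,
    hough_accumulator,
    render_lines,
)
from cropseg.synthetic import SceneSpec, gap_centerlines, make_scene


def brute_force_accumulator(edge_bits, thetas, dists):
    """Independent double-loop Hough voting with round-half-away binning."""
    acc = np.zeros((len(dists), len(thetas)), dtype=np.int64)
    offset = int(dists[0])
    ys, xs = np.nonzero(edge_bits)
    for x, y in zip(xs, ys):
        for j, t in enumerate(thetas):
            v = x * np.cos(t) + y * np.sin(t)
            b = int(np.floor(v + 0.5)) if v >= 0 else int(np.ceil(v - 0.5))
            acc[b - offset, j] += 1
    return acc


def map_line_to_array(line, transform):
    """(r, theta) of a map-coordinate LineString in array pixel convention."""
    (x0, y0), (x1, y1) = list(line.coords)
    # continuous pixel coords of the endpoints
    cx0 = (x0 - transform.origin_x) / transform.xres - 0.5
    cy0 = (y0 - transform.origin_y) / transform.yres - 0.5
    cx1 = (x1 - transform.origin_x) / transform.xres - 0.5
    cy1 = (y1 - transform.origin_y) / transform.yres - 0.5
    d = np.array([cx1 - cx0, cy1 - cy0])
    n = np.array([-d[1], d[0]])
    n = n / np.hypot(*n)
    r = n @ np.array([cx0, cy0])
    theta = np.arctan2(n[1], n[0])
    if not (-np.pi / 2 <= theta < np.pi / 2):  # canonical normal-angle range
        theta = theta - np.pi * np.sign(theta)
        r = -r
    return float(r), float(theta)


class TestEstimateAxes:
    def test_axis_aligned_rectangle(self):
        bits = np.zeros((120, 260), dtype=bool)
        bits[30:80, 20:220] = True  # 200 wide x 50 tall
        axes = estimate_axes(FieldMask(bits))
        assert axes.major_deg == pytest.approx(0.0, abs=0.01)
        assert axes.minor_deg == pytest.approx(90.0, abs=0.01)

    def test_rotated_rectangle_within_half_degree(self):
        gt = GeoTransform(0.0, 512.0, 1.0, -1.0)
        rect = affinity.rotate(shapely.box(100, 180, 400, 280), 30.0, origin=(256, 256))
        bits = rasterize_polygons([rect], (512, 512), gt)
        axes = estimate_axes(FieldMask(bits))
        assert (-axes.major_deg) % 180 == pytest.approx(30.0, abs=0.5)

    def test_square_tie_break_deterministic(self):
        bits = np.zeros((64, 64), dtype=bool)
        bits[10:50, 10:50] = True
        results = {estimate_axes(FieldMask(bits)).major_deg for _ in range(5)}
        assert len(results) == 1
        assert results.pop() in (0.0, 90.0)

    def test_tiny_mask_rejected(self):
        bits = np.zeros((8, 8), dtype=bool)
        bits[2, 2] = bits[3, 3] = True
        with pytest.raises(ValueError):
            estimate_axes(FieldMask(bits))

    def test_minor_is_major_plus_ninety(self):
        for deg in (0.0, 17.0, 95.5, 179.0):
            axes = AxisOrientation(major_deg=deg)
            assert (axes.minor_deg - axes.major_deg) % 180 == pytest.approx(90.0)


class TestAccumulator:
    def test_matches_brute_force_bin_for_bin(self):
        rng = np.random.default_rng(3)
        for _ in range(4):
            bits = rng.random((48, 64)) < 0.05
            thetas = np.deg2rad(np.sort(rng.uniform(-89.9, 89.9, 15)))
            acc, th, dists = hough_accumulator(bits, thetas)
            assert np.array_equal(acc, brute_force_accumulator(bits, th, dists))


class TestConstrainedHough:
    def test_single_ideal_line_detected_once(self):
        bits = np.zeros((96, 96), dtype=bool)
        bits[20, 8:88] = True  # 80 collinear pixels parallel to the 0-deg axis
        ls = constrained_hough(EdgeMap(bits, CannyParams()), AxisOrientation(0.0), "major")
        assert len(ls) == 1
        line = ls.lines[0]
        xs = np.arange(8, 88)
        assert line.distance_to(xs, np.full_like(xs, 20)).max() <= 1.0

    def test_perpendicular_axis_request_empty(self):
        bits = np.zeros((96, 96), dtype=bool)
        bits[20, 8:88] = True
        ls = constrained_hough(EdgeMap(bits, CannyParams()), AxisOrientation(0.0), "minor")
        assert len(ls) == 0

    def test_empty_edges_warns_not_raises(self):
        ls = constrained_hough(
            EdgeMap(np.zeros((32, 32), bool), CannyParams()), AxisOrientation(10.0), "major"
        )
        assert len(ls) == 0

    def test_scene_divisions_all_matched(self):
        spec = SceneSpec(rows=4, cols=6, angle_deg=17.0, seed=1)
        image, aoi, _ = make_scene(spec)
        mask = rasterize_aoi(aoi, image)
        em = canny_edges(image, CannyParams(sigma=2), mask)
        axes = estimate_axes(mask)
        detected = list(constrained_hough(em, axes, "major")) + list(
            constrained_hough(em, axes, "minor")
        )
        # at least one division line per grid boundary in each direction
        v_lines = [l for l, tag in gap_centerlines(spec) if tag == "v"]
        h_lines = [l for l, tag in gap_centerlines(spec) if tag == "h"]
        assert len(v_lines) == spec.cols + 1 and len(h_lines) == spec.rows + 1
        offsets = []
        h_img, w_img = image.shape
        cx, cy = (w_img - 1) / 2, (h_img - 1) / 2
        for true_line in v_lines + h_lines:
            r_t, th_t = map_line_to_array(true_line, image.transform)
            rc_t = r_t - (cx * np.cos(th_t) + cy * np.sin(th_t))
            best = np.inf
            for d in detected:
                dth = abs(d.theta - th_t)
                flip = dth > np.pi / 2
                if min(dth, np.pi - dth) > np.deg2rad(5):
                    continue
                rc_d = d.r - (cx * np.cos(d.theta) + cy * np.sin(d.theta))
                if flip:
                    rc_d = -rc_d
                best = min(best, abs(rc_d - rc_t))
            offsets.append(best)
        assert np.median(offsets) <= 3.0
        assert len(detected) >= len(v_lines) + len(h_lines)

    def test_angles_stay_inside_axis_window(self):
        spec = SceneSpec(rows=3, cols=3, angle_deg=29.0, seed=0)
        image, aoi, _ = make_scene(spec)
        mask = rasterize_aoi(aoi, image)
        em = canny_edges(image, CannyParams(sigma=2), mask)
        axes = estimate_axes(mask)
        for axis in ("major", "minor"):
            normal = np.deg2rad(axes.angle(axis) - 90.0)
            for line in constrained_hough(em, axes, axis, tolerance_deg=5.0):
                d = abs(line.theta - normal) % np.pi
                assert min(d, np.pi - d) <= np.deg2rad(5.0) + 1e-9

    def test_rotation_equivariance(self):
        angles = {}
        for rot in (5.0, 20.0):
            spec = SceneSpec(rows=3, cols=4, angle_deg=rot, seed=1)
            image, aoi, _ = make_scene(spec)
            mask = rasterize_aoi(aoi, image)
            em = canny_edges(image, CannyParams(sigma=2), mask)
            ls = constrained_hough(em, estimate_axes(mask), "major")
            angles[rot] = np.median([np.rad2deg(l.theta) % 180 for l in ls])
        shift = (angles[20.0] - angles[5.0]) % 180
        shift = min(shift, 180 - shift)
        # map rotation is clockwise in array angles; compare magnitude
        assert shift == pytest.approx(15.0, abs=1.0)

    def test_tolerance_bounds_validated(self):
        em = EdgeMap(np.ones((8, 8), bool), CannyParams())
        with pytest.raises(ValueError):
            constrained_hough(em, AxisOrientation(0.0), "major", tolerance_deg=60.0)


class TestRenderLines:
    def test_horizontal_line_exact_row(self):
        ls = LineSet(lines=[HoughLine(r=-5.0, theta=-np.pi / 2, votes=10, axis_tag="major")])
        out = render_lines(ls, (10, 10), width_px=1)
        assert out.sum() == 10
        assert out[5].all()

    def test_perpendicular_overlap_single_pixel(self):
        ls = LineSet(
            lines=[
                HoughLine(r=-5.0, theta=-np.pi / 2, votes=1, axis_tag="major"),
                HoughLine(r=3.0, theta=0.0, votes=1, axis_tag="minor"),
            ]
        )
        out = render_lines(ls, (10, 10), width_px=1)
        assert out.sum() == 10 + 10 - 1

    def test_matches_distance_oracle(self):
        rng = np.random.default_rng(5)
        lines = [
            HoughLine(
                r=float(rng.uniform(-20, 40)),
                theta=float(rng.uniform(-np.pi / 2, np.pi / 2)),
                votes=1,
                axis_tag="major",
            )
            for _ in range(4)
        ]
        out = render_lines(LineSet(lines=lines), (32, 32), width_px=2)
        for r in range(32):
            for c in range(32):
                d = min(abs(c * np.cos(l.theta) + r * np.sin(l.theta) - l.r) for l in lines)
                assert out[r, c] == (d <= 1.0)
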
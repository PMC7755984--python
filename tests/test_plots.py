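"""Segment formation, area filtering, polygonization and the full pipeline."""

import warnings

import numpy as np
import pytest

from cropseg.geo_io import FieldMask, GeoTransform
from cropseg.plots import (
    PipelineConfig,
    SegmentLabels,
    build_segments,
    filter_by_area,
    polygonize,
    segment_plots,
)
from cropseg.synthetic import SceneSpec, make_scene


class TestBuildSegments:
    def test_three_by_three_grid(self):
        mask = FieldMask(np.ones((30, 30), dtype=bool))
        lines = np.zeros((30, 30), dtype=bool)
        lines[[10, 20], :] = True
        lines[:, [10, 20]] = True
        segs = build_segments(lines, mask, 1.0)
        assert segs.n_segments == 9

    def test_no_lines_single_segment(self):
        mask = FieldMask(np.ones((10, 10), dtype=bool))
        segs = build_segments(np.zeros((10, 10), dtype=bool), mask, 1.0)
        assert segs.n_segments == 1
        assert (segs.labels == 1).sum() == 100

    def test_all_lines_warns(self):
        mask = FieldMask(np.ones((5, 5), dtype=bool))
        with pytest.warns(UserWarning, match="no enclosed areas"):
            segs = build_segments(np.ones((5, 5), dtype=bool), mask, 1.0)
        assert segs.n_segments == 0

    def test_diagonal_crossings_still_separate(self):
        # a 1-px diagonal line leaks under 8-connectivity but not 4
        mask = FieldMask(np.ones((9, 9), dtype=bool))
        lines = np.eye(9, dtype=bool)
        segs = build_segments(lines, mask, 1.0)
        assert segs.n_segments == 2


class TestFilterByArea:
    def test_small_plot_removed_at_preset_minimum(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[:10, :10] = 1  # 100 px at 0.01 m2/px = 1.0 m2
        labels[12:, 12:] = 2  # 64 px = 0.64 m2
        segs = SegmentLabels(labels, pixel_area_m2=0.01)
        out = filter_by_area(segs, min_area_m2=3.5)
        assert out.n_segments == 0

    def test_identity_when_min_below_everything(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[:10, :10] = 1
        segs = SegmentLabels(labels, pixel_area_m2=1.0)
        out = filter_by_area(segs, min_area_m2=0.5)
        assert np.array_equal(out.labels, segs.labels)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(11)
        from scipy import ndimage as ndi

        for _ in range(10):
            raw = (rng.random((40, 40)) < 0.6).astype(int)
            labels, _ = ndi.label(raw)
            segs = SegmentLabels(labels, pixel_area_m2=0.25)
            lo, hi = sorted(rng.uniform(0.25, 20.0, 2))
            out = filter_by_area(segs, lo, hi)
            survivors = set()
            for k in range(1, labels.max() + 1):
                area = (labels == k).sum() * 0.25
                if lo <= area <= hi:
                    survivors.add(k)
            assert out.n_segments == len(survivors)
            # every surviving pixel set equals one original label's set
            for k2 in range(1, out.n_segments + 1):
                orig = labels[out.labels == k2]
                assert len(set(orig)) == 1 and orig[0] in survivors

    def test_monotone_in_min_area(self):
        rng = np.random.default_rng(12)
        from scipy import ndimage as ndi

        labels, _ = ndi.label(rng.random((50, 50)) < 0.55)
        segs = SegmentLabels(labels, pixel_area_m2=1.0)
        counts = [filter_by_area(segs, m).n_segments for m in (1, 5, 10, 20, 50)]
        assert counts == sorted(counts, reverse=True)

    def test_labels_consecutive(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[0, :3] = 1
        labels[5, :9] = 2
        labels[9, :2] = 3
        out = filter_by_area(SegmentLabels(labels, 1.0), min_area_m2=4.0)
        assert sorted(np.unique(out.labels)) == [0, 1]

    def test_bad_bounds_rejected(self):
        segs = SegmentLabels(np.ones((4, 4), dtype=int), 1.0)
        with pytest.raises(ValueError):
            filter_by_area(segs, 0.0)
        with pytest.raises(ValueError):
            filter_by_area(segs, 5.0, 2.0)


class TestPolygonize:
    def test_square_label(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[5:15, 5:15] = 1
        gt = GeoTransform(0.0, 0.4, 0.02, -0.02)
        out = polygonize(SegmentLabels(labels, gt.pixel_area_m2), gt)
        assert len(out) == 1
        assert out[0].area_m2 == pytest.approx(0.04)
        assert out[0].polygon.area == pytest.approx(0.04)

    def test_l_shape_six_corners(self, unit_grid):
        labels = np.zeros((12, 12), dtype=int)
        labels[2:10, 2:5] = 1
        labels[7:10, 2:10] = 1
        out = polygonize(SegmentLabels(labels, 1.0), unit_grid)
        assert len(out) == 1
        poly = out[0].polygon
        assert poly.is_valid and len(poly.interiors) == 0
        assert len(poly.exterior.coords) - 1 == 6

    def test_area_conservation_random_labels(self, unit_grid):
        rng = np.random.default_rng(13)
        from scipy import ndimage as ndi

        labels, _ = ndi.label(rng.random((40, 40)) < 0.5)
        segs = SegmentLabels(labels, pixel_area_m2=1.0)
        out = polygonize(segs, unit_grid)
        assert sum(s.area_m2 for s in out) == pytest.approx((labels > 0).sum())
        for s in out:
            assert s.polygon.area == pytest.approx(s.area_m2, rel=1e-9)


class TestSegmentPlots:
    def test_clean_scene_recovers_every_plot(self, standard_scene):
        _, image, aoi, truth = standard_scene
        segments, diag = segment_plots(image, aoi, PipelineConfig(min_area_m2=3.5))
        assert len(segments) == len(truth) == 60
        assert diag.labels.n_segments == 60

    def test_oversized_min_area_removes_all(self, small_scene):
        _, image, aoi, _ = small_scene
        with pytest.warns(UserWarning, match="zero segments"):
            segments, _ = segment_plots(image, aoi, PipelineConfig(min_area_m2=1000.0))
        assert segments == []

    def test_segments_disjoint_and_inside_mask(self, small_scene):
        _, image, aoi, _ = small_scene
        segments, diag = segment_plots(image, aoi, PipelineConfig(min_area_m2=3.5))
        labels = diag.labels.labels
        assert (labels > 0).sum() == sum(
            round(s.area_m2 / image.pixel_area_m2) for s in segments
        )
        assert not (labels > 0)[~diag.mask.bits].any()

    def test_deterministic_output(self, small_scene):
        _, image, aoi, _ = small_scene
        a, _ = segment_plots(image, aoi, PipelineConfig(min_area_m2=3.5))
        b, _ = segment_plots(image, aoi, PipelineConfig(min_area_m2=3.5))
        assert len(a) == len(b)
        for s, t in zip(a, b):
            assert s.polygon.equals_exact(t.polygon, 0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PipelineConfig(edge_algorithm="XX")
        with pytest.raises(ValueError):
            PipelineConfig(min_area_m2=5.0, max_area_m2=2.0)
        with pytest.raises(ValueError):
            PipelineConfig(refine="sharpen")
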
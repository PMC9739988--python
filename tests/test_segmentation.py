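"""Watershed cell detection on synthetic tiles with exact ground truth."""

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from tilquant.segmentation import (
    CellClass,
    DetectionParams,
    count_and_area,
    detect_cells,
    resample_to_working_resolution,
)
from tilquant.stain import deconvolve, rgb_to_od
from tilquant.synthetic import ClassPhenotype, SceneSpec, generate_tile

from conftest import greedy_match


def _hema(spec, stain_model):
    image, truth = generate_tile(spec)
    channels = deconvolve(rgb_to_od(image, 255.0), stain_model)
    return channels[:, :, 0], truth


def _single_class_spec(area, peak, n, seed=3, tile=200.0):
    return SceneSpec(
        seed=seed,
        tile_size_um=tile,
        cell_counts={"TUMOR": n},
        phenotypes={"TUMOR": ClassPhenotype((area, area), (0.0, 0.0), (peak, peak))},
    )


class TestResample:
    def test_factor_two_geometry(self):
        img = np.random.default_rng(0).random((1000, 1000))
        out = resample_to_working_resolution(img, 0.25, 0.5)
        assert out.shape == (500, 500)

    def test_identity_when_sizes_match(self):
        img = np.random.default_rng(0).random((64, 64))
        assert resample_to_working_resolution(img, 0.5, 0.5) is img

    def test_constant_image_preserved(self):
        img = np.full((80, 80), 3.7)
        out = resample_to_working_resolution(img, 0.25, 0.5)
        np.testing.assert_allclose(out, 3.7, rtol=1e-6)

    def test_rejects_nonpositive_pixel_size(self):
        with pytest.raises(ValueError):
            resample_to_working_resolution(np.ones((4, 4)), 0.0, 0.5)


class TestDetectCells:
    def test_twenty_disjoint_nuclei_recovered(self, stain_model):
        # 20 circular nuclei, 50 um^2 at peak OD 0.8: every one detected,
        # centroids within 1 um, areas within 20%.
        hema, truth = _hema(_single_class_spec(50.0, 0.8, 20), stain_model)
        dets = detect_cells(hema, DetectionParams())
        assert len(dets) == 20
        matches = greedy_match(dets, truth)
        assert len(matches) == 20
        for ti, di in matches.items():
            dx = dets[di].centroid[0] - truth["x_um"].iloc[ti]
            dy = dets[di].centroid[1] - truth["y_um"].iloc[ti]
            assert np.hypot(dx, dy) < 1.0
            assert dets[di].nucleus_area_um2 == pytest.approx(
                truth["nucleus_area_um2"].iloc[ti], rel=0.2
            )

    def test_blob_below_minimum_area_rejected(self, stain_model):
        hema, _ = _hema(_single_class_spec(5.0, 0.8, 1, tile=60.0), stain_model)
        assert detect_cells(hema, DetectionParams()) == []

    def test_blob_above_maximum_area_rejected(self, stain_model):
        hema, _ = _hema(_single_class_spec(500.0, 0.8, 1, tile=120.0), stain_model)
        assert detect_cells(hema, DetectionParams()) == []

    def test_area_filter_bounds_hold(self, tile_detections):
        params = DetectionParams()
        for det in tile_detections:
            assert (
                params.min_cell_area_um2
                <= det.nucleus_area_um2
                <= params.max_cell_area_um2
            )

    def test_precision_recall_on_default_scene(self, default_tile, tile_detections):
        _, _, truth = default_tile
        matches = greedy_match(tile_detections, truth)
        precision = len(matches) / len(tile_detections)
        recall = len(matches) / len(truth)
        assert precision >= 0.9
        assert recall >= 0.9

    def test_cell_polygons_interior_disjoint(self, tile_detections):
        # The distance-limited Voronoi expansion never lets cells overlap.
        dets = tile_detections
        centroids = np.array([d.centroid for d in dets])
        for i in range(len(dets)):
            near = np.flatnonzero(
                np.hypot(*(centroids - centroids[i]).T) < 25.0
            )
            for j in near:
                if j <= i:
                    continue
                inter = dets[i].cell_polygon.intersection(dets[j].cell_polygon)
                assert inter.area < 1e-6 * dets[i].cell_polygon.area + 1e-9

    def test_nucleus_contained_in_cell(self, tile_detections):
        for det in tile_detections:
            assert det.nucleus_polygon.within(det.cell_polygon.buffer(0.51))
            assert det.nucleus_area_um2 <= det.cell_area_um2 + 1e-6

    def test_translation_equivariance(self, stain_model):
        spec = _single_class_spec(50.0, 0.8, 10, seed=5, tile=150.0)
        hema, _ = _hema(spec, stain_model)
        pad = 40
        canvas = np.zeros((hema.shape[0] + 2 * pad, hema.shape[1] + 2 * pad))
        canvas[pad:-pad, pad:-pad] = hema
        base = detect_cells(canvas, DetectionParams())
        shift = 16  # pixels
        shifted = np.roll(canvas, (shift, shift), axis=(0, 1))
        moved = detect_cells(shifted, DetectionParams())
        assert len(base) == len(moved)
        d_um = shift * 0.5
        expect = sorted((x + d_um, y + d_um) for x, y in (d.centroid for d in base))
        got = sorted(d.centroid for d in moved)
        np.testing.assert_allclose(got, expect, atol=0.5)

    def test_roi_filters_detections(self, tile_channels):
        roi = box(0.0, 0.0, 160.0, 160.0)  # one quadrant of the 320 um tile
        dets = detect_cells(tile_channels[:, :, 0], DetectionParams(), roi)
        assert len(dets) > 0
        for det in dets:
            assert 0 <= det.centroid[0] <= 160.0
            assert 0 <= det.centroid[1] <= 160.0

    def test_deterministic_ordering(self, tile_detections):
        keys = [(d.centroid[1], d.centroid[0]) for d in tile_detections]
        assert keys == sorted(keys)
        assert [d.id for d in tile_detections] == list(range(len(tile_detections)))

    def test_rejects_negative_raster(self):
        with pytest.raises(ValueError, match="negative"):
            detect_cells(np.full((10, 10), -0.1), DetectionParams())

    def test_rejects_empty_roi(self):
        with pytest.raises(ValueError, match="roi"):
            detect_cells(np.zeros((10, 10)), DetectionParams(), Polygon())

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DetectionParams(min_cell_area_um2=500.0, max_cell_area_um2=400.0)
        with pytest.raises(ValueError):
            DetectionParams(od_threshold=0.0)


class TestCountAndArea:
    def test_counts_by_class(self, tile_detections):
        dets = [d for d in tile_detections[:5]]
        for d in dets[:3]:
            d.class_label = CellClass.TUMOR
        for d in dets[3:]:
            d.class_label = CellClass.IMMUNE
        counts, area = count_and_area(dets, box(0, 0, 1000.0, 1000.0))
        assert counts["TUMOR"] == 3
        assert counts["IMMUNE"] == 2
        assert area == pytest.approx(1.0)

    def test_empty_detections(self):
        counts, area = count_and_area([], box(0, 0, 500.0, 500.0))
        assert sum(counts.values()) == 0
        assert area == pytest.approx(0.25)
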
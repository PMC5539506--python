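import numpy as np
import pytest

from phstrip.roi import (
    Contour,
    DetectionConfig,
    DetectionError,
    detect_edges,
    detect_scene,
    draw_overlay,
    extract_initial_contours,
    label_contours,
    place_sampling_grid,
    retrieve_colors,
    simplify,
)
from phstrip.synthetic import CameraModel, render_chart_capture

from conftest import rectangle_boundary

import scipy.ndimage as ndi

CFG = DetectionConfig()


def count_regions(edges, min_area=300):
    filled = ndi.binary_fill_holes(edges)
    labels, n = ndi.label(filled)
    areas = ndi.sum(np.ones_like(labels), labels, range(1, n + 1))
    return int((areas >= min_area).sum())


class TestSimplify:
    def test_constant_image_unchanged(self):
        img = np.full((32, 32, 3), 77, dtype=np.uint8)
        np.testing.assert_array_equal(simplify(img, CFG), img)

    def test_salt_and_pepper_removed(self):
        img = np.full((40, 40, 3), 120, dtype=np.uint8)
        noisy = img.copy()
        rng = np.random.default_rng(0)
        ys, xs = rng.integers(2, 38, 10), rng.integers(2, 38, 10)
        noisy[ys, xs] = 255
        noisy[ys + 1, xs] = 0
        np.testing.assert_array_equal(simplify(noisy, CFG), img)

    def test_kernel_larger_than_image(self):
        with pytest.raises(ValueError):
            simplify(np.zeros((3, 3, 3), dtype=np.uint8), CFG)

    def test_noise_sigma8_same_region_count(self, palette):
        clean, _ = render_chart_capture(palette, CameraModel(), 7, seed=0)
        noisy, _ = render_chart_capture(palette, CameraModel(noise_sigma=8.0), 7, seed=0)
        n_clean = count_regions(detect_edges(simplify(clean, CFG), CFG))
        n_noisy = count_regions(detect_edges(simplify(noisy, CFG), CFG))
        assert n_noisy == n_clean


class TestDetectEdges:
    def test_constant_image_has_no_edges(self):
        img = np.full((64, 64, 3), 150, dtype=np.uint8)
        assert detect_edges(img, CFG).sum() == 0

    def test_all_drawn_rectangles_have_closed_boundaries(self, identity_scene):
        img, gt = identity_scene
        edges = detect_edges(simplify(img, CFG), CFG)
        filled = ndi.binary_fill_holes(edges)
        labels, _ = ndi.label(filled)
        hit = {labels[int(round(y)), int(round(x))] for x, y in gt.region_centers()}
        assert 0 not in hit  # every region center lies inside a filled blob
        assert len(hit) == 6  # and the six blobs are distinct

    def test_closing_does_not_reduce_closed_regions(self, identity_scene):
        img, _ = identity_scene
        from skimage import feature

        gray = simplify(img, CFG).max(axis=-1) / 255.0
        raw = feature.canny(
            gray, sigma=CFG.canny_sigma,
            low_threshold=CFG.canny_low, high_threshold=CFG.canny_high,
        )
        closed = detect_edges(simplify(img, CFG), CFG)
        assert count_regions(closed) >= count_regions(raw)


class TestExtractInitialContours:
    def test_scene_contours_found(self, identity_scene):
        img, gt = identity_scene
        edges = detect_edges(simplify(img, CFG), CFG)
        contours = extract_initial_contours(edges, CFG)
        assert len(contours) >= 6
        centers = np.array([c.center for c in contours])
        for truth in gt.region_centers():
            assert np.linalg.norm(centers - truth, axis=1).min() < 3.0

    def test_star_blob_rejected(self, palette):
        img, _ = render_chart_capture(palette, CameraModel(), 7, seed=0)
        img = img.copy()
        # paint a filled non-convex star near the lower-left corner
        cy, cx, r1, r2 = 680, 80, 30, 12
        ang = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        pts = np.stack(
            [cx + np.where(np.arange(10) % 2 == 0, r1, r2) * np.cos(ang),
             cy + np.where(np.arange(10) % 2 == 0, r1, r2) * np.sin(ang)], axis=1
        )
        from skimage.draw import polygon

        rr, cc = polygon(pts[:, 1], pts[:, 0], img.shape[:2])
        img[rr, cc] = (10, 10, 10)
        edges = detect_edges(simplify(img, CFG), CFG)
        contours = extract_initial_contours(edges, CFG)
        centers = np.array([c.center for c in contours])
        assert np.linalg.norm(centers - [cx, cy], axis=1).min() > 10

    def test_small_speck_rejected(self, palette):
        img, _ = render_chart_capture(palette, CameraModel(), 7, seed=0)
        img = img.copy()
        img[700:703, 40:43] = 0
        edges = detect_edges(simplify(img, CFG), CFG)
        contours = extract_initial_contours(edges, CFG)
        centers = np.array([c.center for c in contours])
        assert np.linalg.norm(centers - [41, 701], axis=1).min() > 10

    def test_empty_edge_map_gives_empty_list(self):
        assert extract_initial_contours(np.zeros((60, 60), dtype=bool), CFG) == []


def scene_contours(shape=(720, 960)):
    """Synthetic contour list mimicking the nominal scene layout."""
    refs = [rectangle_boundary(264, 93, 432, 114), rectangle_boundary(264, 513, 432, 114)]
    tgts = [rectangle_boundary(464, y - 16, 32, 32) for y in (288, 336, 384, 432)]
    contours = [Contour.from_boundary(b, CFG.polygon_epsilon) for b in refs + tgts]
    assert all(c is not None for c in contours)
    return contours


class TestLabelContours:
    def test_clean_scene_labeling(self):
        layout = label_contours(scene_contours(), CFG, (720, 960))
        assert layout.upper_reference.center[1] < 300
        assert layout.lower_reference.center[1] > 400
        ys = [c.center[1] for c in layout.target_contours]
        assert ys == sorted(ys)  # k = 1..4 top to bottom

    def test_nested_duplicate_suppressed(self):
        contours = scene_contours()
        inner = Contour.from_boundary(
            rectangle_boundary(468, 276, 24, 24), CFG.polygon_epsilon
        )
        layout = label_contours(contours + [inner], CFG, (720, 960))
        assert len(layout.target_contours) == 4
        areas = [c.area for c in layout.target_contours]
        assert min(areas) > inner.area  # the outer squares won

    def test_odd_sized_square_rejected_by_cluster(self):
        contours = scene_contours()
        odd = Contour.from_boundary(
            rectangle_boundary(440, 330, 70, 64), CFG.polygon_epsilon
        )
        # five square-ish candidates near the line; the largest consistent
        # cluster (the four patches) survives
        layout = label_contours(contours + [odd], CFG, (720, 960))
        assert len(layout.target_contours) == 4
        assert all(c.area < 2000 for c in layout.target_contours)

    def test_too_few_references_is_structured_error(self):
        contours = scene_contours()[1:]  # drop the upper reference
        with pytest.raises(DetectionError, match="reference"):
            label_contours(contours, CFG, (720, 960))

    def test_wrong_target_count_is_structured_error(self):
        contours = scene_contours()[:5]  # only three targets
        with pytest.raises(DetectionError, match="target"):
            label_contours(contours, CFG, (720, 960))

    def test_empty_list_rejected(self):
        with pytest.raises(DetectionError):
            label_contours([], CFG, (720, 960))


class TestSamplingGridAndColors:
    def test_axis_aligned_grid_within_one_pixel(self, palette, identity_scene):
        img, gt = identity_scene
        layout, grid, tgt = detect_scene(img)
        assert np.abs(layout.reference_positions - gt.reference_positions).max() < 1.0
        assert np.abs(layout.target_positions - gt.target_positions).max() < 1.0

    def test_translation_equivariance(self, palette, identity_scene):
        img0, _ = identity_scene
        layout0, _, _ = detect_scene(img0)
        img, _ = render_chart_capture(palette, CameraModel(translation=(7, -4)), 7, seed=1)
        layout, _, _ = detect_scene(img)
        shift = layout.reference_positions - layout0.reference_positions
        assert np.abs(shift - np.array([7.0, -4.0])).max() < 1.0

    def test_rotated_grid_within_two_pixels(self, palette):
        img, gt = render_chart_capture(palette, CameraModel(rotation_deg=5), 7, seed=1)
        layout, _, _ = detect_scene(img)
        assert np.abs(layout.reference_positions - gt.reference_positions).max() < 2.0

    def test_retrieved_colors_match_palette(self, identity_scene):
        img, gt = identity_scene
        _, grid, tgt = detect_scene(img)
        assert np.abs(grid.colors - gt.reference_uv_image).max() < 1e-3
        assert np.abs(tgt.colors - gt.target_uv_image).max() < 1e-3
        # identity camera: image colors equal the palette ground truth
        assert np.abs(grid.colors - gt.reference_uv_true).max() < 1e-3

    def test_grid_ordering_deterministic(self, identity_scene):
        img, _ = identity_scene
        _, grid1, _ = detect_scene(img)
        _, grid2, _ = detect_scene(img)
        np.testing.assert_array_equal(grid1.colors, grid2.colors)

    def test_zero_sample_window_is_legal(self, identity_scene):
        img, _ = identity_scene
        cfg = DetectionConfig(sample_window=0)
        layout, grid, tgt = detect_scene(img, cfg)
        assert np.all(np.isfinite(grid.colors))

    def test_positions_required_before_retrieval(self, identity_scene):
        img, _ = identity_scene
        edges = detect_edges(simplify(img, CFG), CFG)
        layout = label_contours(extract_initial_contours(edges, CFG), CFG, img.shape[:2])
        with pytest.raises(ValueError, match="positions"):
            retrieve_colors(img, layout, CFG)


class TestEquivarianceSweep:
    @pytest.mark.parametrize(
        "camera",
        [
            CameraModel(rotation_deg=10),
            CameraModel(rotation_deg=-10),
            CameraModel(translation=(20, -20)),
            CameraModel(translation=(-20, 20)),
            CameraModel(scale=0.9),
            CameraModel(scale=1.1),
            CameraModel(rotation_deg=6, translation=(10, 10), scale=1.05),
        ],
    )
    def test_color_retrieval_stable(self, palette, camera):
        img, gt = render_chart_capture(palette, camera, 7, seed=1)
        layout, grid, tgt = detect_scene(img)
        assert np.abs(grid.colors - gt.reference_uv_image).max() < 1e-2
        assert np.abs(tgt.colors - gt.target_uv_image).max() < 1e-2


class TestConfigAndOverlay:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"median_kernel": 4},
            {"canny_low": 0.2, "canny_high": 0.1},
            {"sample_window": -1},
            {"min_contour_area": 0},
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            DetectionConfig(**kwargs)

    def test_overlay_and_layout_json(self, identity_scene):
        img, _ = identity_scene
        layout, _, _ = detect_scene(img)
        overlay = draw_overlay(img, layout)
        assert overlay.shape == img.shape
        assert (overlay != img).any()
        d = layout.to_dict()
        assert len(d["targets"]) == 4
        assert np.asarray(d["reference_positions"]).shape == (12, 18, 2)
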
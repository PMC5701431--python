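"""Phases 2-3: pupil localization, iris radius and ROI extraction."""

import numpy as np
import pytest
from scipy import ndimage

from conftest import small_scene
from lipilyzer.frames import pixel_brightness
from lipilyzer.geometry import (
    EmptyROIError,
    GeometryConfig,
    choose_eye_center,
    compute_geometry,
    extract_roi,
    find_darkest_seed,
    flood_fill,
    mask_centroid,
    refine_pupil,
)
from lipilyzer.synthetic import render_frame

SMALL_CONFIG = GeometryConfig(expected_radius=60.0)


def bfs_flood_oracle(brightness, seed, threshold):
    """Independent breadth-first flood fill with 8-neighbour moves."""
    h, w = brightness.shape
    ref = brightness[seed]
    visited = np.zeros((h, w), dtype=bool)
    queue = [seed]
    visited[seed] = True
    while queue:
        r, c = queue.pop()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and not visited[rr, cc]:
                    if abs(brightness[rr, cc] - ref) < threshold:
                        visited[rr, cc] = True
                        queue.append((rr, cc))
    return visited


class TestDarkestSeed:
    def test_uniform_frame_tie_breaks_top_left(self):
        frame = np.full((40, 40, 3), 90, dtype=np.uint8)
        assert find_darkest_seed(frame, window=21) == (10, 10)

    def test_matches_exhaustive_scan(self, rng):
        frame = rng.integers(0, 256, size=(40, 40, 3), dtype=np.uint8)
        window = 21
        sums = ndimage.uniform_filter(
            pixel_brightness(frame), size=window, mode="constant"
        )
        # brute force: evaluate every fully-contained window
        best = None
        for top in range(40 - window + 1):
            for left in range(40 - window + 1):
                s = pixel_brightness(frame[top : top + window, left : left + window]).mean()
                if best is None or s < best[0] - 1e-12:
                    best = (s, top + window // 2, left + window // 2)
        assert find_darkest_seed(frame, window) == best[1:]

    def test_lands_inside_synthetic_pupil(self, lut):
        frame, labels = render_frame(small_scene(), 0, lut)
        seed = np.array(find_darkest_seed(frame))
        center = np.array(labels["eye_center"])
        assert np.hypot(*(seed - center)) <= labels["pupil_radius"]

    def test_too_small_frame_rejected(self):
        with pytest.raises(ValueError):
            find_darkest_seed(np.zeros((10, 10, 3), dtype=np.uint8), window=21)


class TestFloodFill:
    def test_uniform_image_fills_everything(self):
        img = np.full((12, 15), 40.0)
        assert flood_fill(img, (3, 3), threshold=1.0).all()

    def test_step_edge_confines_region(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 100.0
        mask = flood_fill(img, (0, 0), threshold=10.0)
        assert mask[:, :5].all() and not mask[:, 5:].any()

    def test_matches_bfs_oracle_on_noise(self, rng):
        for _ in range(10):
            img = rng.integers(0, 2, size=(30, 30)).astype(float) * 60
            seed = (int(rng.integers(30)), int(rng.integers(30)))
            assert np.array_equal(
                flood_fill(img, seed, 30.0), bfs_flood_oracle(img, seed, 30.0)
            )

    def test_contains_seed_and_connected(self, rng):
        img = rng.normal(100, 30, size=(25, 25))
        mask = flood_fill(img, (12, 12), threshold=20.0)
        assert mask[12, 12]
        labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
        assert n == 1

    def test_out_of_bounds_seed_rejected(self):
        with pytest.raises(ValueError):
            flood_fill(np.zeros((5, 5)), (9, 0), 1.0)


class TestRefinePupil:
    def _disk(self, shape, center, radius, ragged_rng=None):
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        radii = radius
        img = np.full(shape, 120.0)
        dist = np.hypot(rr - center[0], cc - center[1])
        mask = dist <= radius
        if ragged_rng is not None:
            bumps = dist <= radius + ragged_rng.integers(-4, 5, size=shape)
            mask |= bumps & (dist <= radius + 4)
        img[mask] = 5.0
        return img, mask

    def test_ragged_disk_centroid_recovered(self, rng):
        img, _ = self._disk((120, 120), (60, 58), 25, ragged_rng=rng)
        coarse = flood_fill(img, (60, 58), 10.0)
        refined, centroid = refine_pupil(img, coarse, (60, 58))
        assert np.hypot(centroid[0] - 60, centroid[1] - 58) <= 2.0

    def test_smooth_disk_centroid_stable(self):
        img, _ = self._disk((120, 120), (55, 66), 22)
        coarse = flood_fill(img, (55, 66), 10.0)
        _, before = mask_centroid(coarse), None
        refined, centroid = refine_pupil(img, coarse, (55, 66))
        assert np.hypot(centroid[0] - 55, centroid[1] - 66) <= 0.5

    def test_refined_boundary_not_rougher(self, rng):
        img, _ = self._disk((120, 120), (60, 60), 25, ragged_rng=rng)
        coarse = flood_fill(img, (60, 60), 10.0)
        refined, _ = refine_pupil(img, coarse, (60, 60))

        def roughness(mask):
            eroded = ndimage.binary_erosion(mask)
            perimeter = (mask & ~eroded).sum()
            return perimeter**2 / mask.sum()

        assert roughness(refined) <= roughness(coarse)

    def test_centroid_is_first_moment(self, rng):
        img, _ = self._disk((100, 100), (50, 50), 20, ragged_rng=rng)
        coarse = flood_fill(img, (50, 50), 10.0)
        refined, centroid = refine_pupil(img, coarse, (50, 50))
        rows, cols = np.nonzero(refined)
        assert centroid == pytest.approx((rows.mean(), cols.mean()))

    def test_empty_coarse_mask_rejected(self):
        with pytest.raises(ValueError):
            refine_pupil(np.zeros((10, 10)), np.zeros((10, 10), bool), (5, 5))


class TestChooseEyeCenter:
    def test_coincident_points_use_centroid(self):
        assert choose_eye_center((10.0, 10.0), (10, 10), 5.0) == (10.0, 10.0)

    def test_beyond_limit_falls_back_to_seed(self):
        assert choose_eye_center((10.0, 20.1), (10, 10), 10.0) == (10.0, 10.0)

    def test_exactly_at_limit_is_inclusive(self):
        assert choose_eye_center((10.0, 20.0), (10, 10), 10.0) == (10.0, 20.0)


class TestIrisRadius:
    def test_synthetic_eye_within_5_percent(self, lut):
        frame, labels = render_frame(small_scene(iris_texture_sigma=2.0), 0, lut)
        geometry = compute_geometry(frame, SMALL_CONFIG)
        assert abs(geometry.iris_radius - 60.0) / 60.0 <= 0.05

    def test_robust_to_eyelid_occlusion(self, lut):
        frame, labels = render_frame(
            small_scene(eyelids=True, iris_texture_sigma=2.0), 0, lut
        )
        geometry = compute_geometry(frame, SMALL_CONFIG)
        assert abs(geometry.iris_radius - 60.0) / 60.0 <= 0.05


class TestExtractROI:
    def test_postconditions_hold(self, lut):
        frame, labels = render_frame(small_scene(), 0, lut)
        geometry = compute_geometry(frame, SMALL_CONFIG)
        roi = extract_roi(
            frame, geometry.eye_center, geometry.iris_radius, geometry.pupil_mask
        )
        rows, cols = np.nonzero(roi.mask)
        er, ec = geometry.eye_center
        dist = np.hypot(rows - er, cols - ec)
        inner = 0.8 * geometry.iris_radius
        assert np.all(dist <= inner)                      # (a)
        assert np.all(rows > er)                          # (b)
        assert np.all(np.abs(cols - ec) <= 0.8 * inner)   # (c)
        brightness = pixel_brightness(frame.pixels)
        region = np.zeros(roi.mask.shape, bool)
        rr, cc = np.ogrid[: roi.mask.shape[0], : roi.mask.shape[1]]
        region = (
            (np.hypot(rr - er, cc - ec) <= inner)
            & (rr > er)
            & (np.abs(cc - ec) <= 0.8 * inner)
            & ~geometry.pupil_mask
        )
        assert np.all(brightness[roi.mask] >= brightness[region].mean())  # (d)
        assert not (roi.mask & geometry.pupil_mask).any()

    def test_roi_only_below_center(self, lut):
        frame, labels = render_frame(small_scene(), 0, lut)
        geometry = compute_geometry(frame, SMALL_CONFIG)
        roi = extract_roi(
            frame, geometry.eye_center, geometry.iris_radius, geometry.pupil_mask
        )
        rows = np.nonzero(roi.mask)[0]
        assert rows.min() > geometry.eye_center[0]
        # covers a substantial part of the labelled band
        overlap = (roi.mask & labels["roi_mask"]).sum()
        assert overlap / labels["roi_mask"].sum() > 0.3

    def test_bottom_edge_center_is_degenerate(self):
        frame = np.full((50, 50, 3), 100, dtype=np.uint8)
        with pytest.raises(EmptyROIError):
            extract_roi(frame, (49.0, 25.0), 20.0)


class TestGeometryPipeline:
    def test_deterministic(self, lut):
        frame, _ = render_frame(small_scene(noise_sigma=1.0), 0, lut)
        a = compute_geometry(frame, SMALL_CONFIG)
        b = compute_geometry(frame, SMALL_CONFIG)
        assert np.array_equal(a.pupil_mask, b.pupil_mask)
        assert a.eye_center == b.eye_center and a.iris_radius == b.iris_radius

    def test_roi_count_invariant_under_whole_pixel_translation(self, lut):
        spec = small_scene(eye_path=((100, 130), (104, 123)))
        counts = []
        for i in range(2):
            frame, _ = render_frame(spec, i, lut)
            geometry = compute_geometry(frame, SMALL_CONFIG)
            roi = extract_roi(
                frame, geometry.eye_center, geometry.iris_radius, geometry.pupil_mask
            )
            counts.append(roi.pixel_count)
        assert counts[0] == counts[1]

    def test_tracks_moving_eye(self, lut):
        spec = small_scene(
            eye_path=tuple((100 + 2 * i, 130 - 3 * i) for i in range(5)),
            iris_texture_sigma=2.0,
            noise_sigma=1.0,
        )
        for i in range(5):
            frame, labels = render_frame(spec, i, lut)
            geometry = compute_geometry(frame, SMALL_CONFIG)
            tc = labels["eye_center"]
            err = np.hypot(geometry.eye_center[0] - tc[0], geometry.eye_center[1] - tc[1])
            assert err <= 3.0
            assert abs(geometry.iris_radius - 60.0) / 60.0 <= 0.05
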
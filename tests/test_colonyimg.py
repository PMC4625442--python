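"""Imaging-chain checks: flat-fielding, stitching, segmentation, circles, tracking."""

import numpy as np
import pytest

from pilisort import colonyimg, synthgen
from pilisort.colonyimg import (
    assign_clones,
    estimate_illumination,
    extract_contour,
    fit_circle,
    local_variance,
    normalize_coordinates,
    segment_colonies,
    segment_fluorescence,
    stitch_grid,
    track_colonies,
)
from pilisort.config import ColonySimConfig


class TestIllumination:
    def test_flat_tiles_give_unit_field(self):
        tiles = np.full((12, 32, 32), 7.0)
        field = estimate_illumination(tiles)
        np.testing.assert_allclose(field.raster, 1.0, atol=1e-12)

    def test_generator_field_recovered_within_2pct_rms(self, small_colony_config):
        tiles, _, gt = synthgen.simulate_position_grid(small_colony_config)
        field = estimate_illumination(tiles)
        rms = np.sqrt(np.mean((field.raster - gt.illumination) ** 2))
        assert rms < 0.02

    def test_correction_flattens_tiles(self, small_colony_config):
        tiles, _, gt = synthgen.simulate_position_grid(small_colony_config)
        field = estimate_illumination(tiles)
        corrected = field.correct(tiles.mean(axis=0))
        # large-scale trend after correction below 1% (interior; the smoothing
        # boundary condition distorts the estimate within ~1 scale of the edge)
        from scipy.ndimage import gaussian_filter

        trend = gaussian_filter(corrected, 15)[30:-30, 30:-30]
        assert np.ptp(trend) / trend.mean() < 0.01

    def test_few_positions_warn(self):
        with pytest.warns(UserWarning, match="positions"):
            estimate_illumination(np.ones((3, 16, 16)))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            estimate_illumination(np.zeros((12, 16, 16)))


class TestStitching:
    def test_constant_blocks_exact(self):
        tiles = [np.full((4, 4), v) for v in (1.0, 2.0, 3.0, 4.0)]
        meta = {"grid_shape": (2, 2), "tile_shape": (4, 4), "overlap": 0}
        out = stitch_grid(tiles, meta)
        assert out.shape == (8, 8)
        assert out[0, 0] == 1.0 and out[0, 7] == 2.0 and out[7, 0] == 3.0 and out[7, 7] == 4.0

    def test_missing_tile_raises(self):
        meta = {"grid_shape": (2, 2), "tile_shape": (4, 4)}
        with pytest.raises(ValueError, match="missing"):
            stitch_grid([np.zeros((4, 4))] * 3, meta)

    def test_overlap_with_identical_content_is_seamless(self):
        tiles = [np.full((6, 6), 5.0)] * 4
        meta = {"grid_shape": (2, 2), "tile_shape": (6, 6), "overlap": 2}
        out = stitch_grid(tiles, meta)
        np.testing.assert_allclose(out, 5.0, atol=1e-12)

    def test_grid_extent_matches_configured_field_of_view(self, small_colony_config):
        tiles, meta, _ = synthgen.simulate_position_grid(small_colony_config)
        out = stitch_grid(list(tiles), meta)
        gr, gc = meta["grid_shape"]
        tr, tc = meta["tile_shape"]
        assert out.shape == (gr * tr, gc * tc)


class TestSegmentation:
    def test_constant_image_zero_variance_no_colonies(self):
        img = np.full((64, 64), 3.0)
        assert np.all(local_variance(img) == 0.0)
        assert segment_colonies(img).max() == 0

    def test_variance_invariant_to_additive_constant(self, rng):
        img = rng.normal(0, 1, (64, 64))
        np.testing.assert_allclose(
            local_variance(img), local_variance(img + 100.0), atol=1e-8
        )

    def test_single_speckle_disk_area_within_10pct(self, rng):
        img = np.full((128, 128), 100.0)
        yy, xx = np.mgrid[:128, :128]
        disk = np.hypot(xx - 64, yy - 64) < 25
        img[disk] = 100.0 * (1 + 0.3 * rng.standard_normal(disk.sum()))
        labels = segment_colonies(img)
        assert labels.max() == 1
        area = np.sum(labels == 1)
        assert area == pytest.approx(disk.sum(), rel=0.10)

    def test_two_separated_disks_two_components(self, rng):
        img = np.full((128, 128), 100.0)
        yy, xx = np.mgrid[:128, :128]
        for cx in (32, 96):
            disk = np.hypot(xx - cx, yy - 64) < 15
            img[disk] = 100.0 * (1 + 0.3 * rng.standard_normal(disk.sum()))
        assert segment_colonies(img).max() == 2


class TestContourAndCircle:
    def test_3x3_square_contour_is_its_border(self):
        mask = np.zeros((7, 7), dtype=int)
        mask[2:5, 2:5] = 1
        contour = extract_contour(mask)[1]
        assert len(contour) == 8  # centre pixel survives the erosion

    def test_disk_contour_lies_on_ring(self):
        yy, xx = np.mgrid[:64, :64]
        mask = (np.hypot(xx - 32, yy - 32) <= 20).astype(int)
        contour = extract_contour(mask)[1]
        r = np.hypot(contour[:, 1] - 32, contour[:, 0] - 32)
        assert np.all(np.abs(r - 20) < 1.5)

    def test_empty_mask_empty_contour(self):
        assert extract_contour(np.zeros((8, 8), dtype=int)) == {}

    def test_unit_circle_exact(self):
        pts = np.array([[1, 0], [0, 1], [-1, 0], [0, -1]])  # (row, col)
        cx, cy, r, rms = fit_circle(pts)
        assert (cx, cy) == pytest.approx((0.0, 0.0), abs=1e-12)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert rms < 1e-12

    def test_noise_free_circle_exact_recovery(self):
        theta = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        pts = np.column_stack([7.25 + 41 * np.sin(theta), 5.5 + 41 * np.cos(theta)])
        cx, cy, r, rms = fit_circle(pts)
        assert cx == pytest.approx(5.5, abs=1e-9)
        assert cy == pytest.approx(7.25, abs=1e-9)
        assert r == pytest.approx(41.0, abs=1e-9)

    def test_collinear_and_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_circle(np.array([[0, 0], [1, 1], [2, 2], [3, 3]]))
        with pytest.raises(ValueError):
            fit_circle(np.array([[0, 0], [1, 1]]))

    def test_generator_colony_radius_within_2px(self, small_colony_config):
        bf, _, gt = synthgen.simulate_colony_stack(small_colony_config)
        f = 8
        labels = segment_colonies(bf[f])
        contours = extract_contour(labels)
        pts = max(contours.values(), key=len)
        _, _, r, _ = fit_circle(pts)
        assert abs(r - gt.circles[f, 2]) < 2.0


class TestTracking:
    def test_single_growing_colony_single_valid_track(self):
        circles = [[(50.0, 50.0, 10.0 + f)] for f in range(10)]
        tracks = track_colonies(circles)
        assert len(tracks) == 1
        assert all(tracks[0].valid)

    def test_merging_colonies_invalidated_from_contact(self):
        circles = []
        for f in range(10):
            r = 5.0 + 2.5 * f
            circles.append([(30.0, 50.0, r), (80.0, 50.0, r)])
        tracks = track_colonies(circles)
        assert len(tracks) == 2
        for tr in tracks:
            v = np.asarray(tr.valid)
            assert np.all(v[: v.argmin()]) or v.all()  # prefix property
        # contact when 2·(5 + 2.5f) + margin(3) >= centre distance 50 -> f = 8
        merged_frame = next(f for f in range(10) if 2 * (5.0 + 2.5 * f) + 3.0 >= 50.0)
        assert not tracks[0].valid[merged_frame]
        assert tracks[0].valid[merged_frame - 1]

    def test_teleporting_circle_starts_new_track(self):
        circles = [[(50.0, 50.0, 10.0)], [(50.0, 50.0, 10.5), (200.0, 200.0, 10.0)]]
        tracks = track_colonies(circles)
        assert len(tracks) == 2
        assert tracks[1].frames == [1]


class TestFluorescence:
    def test_zero_fluorescence_empty(self):
        img = np.zeros((64, 64))
        assert segment_fluorescence(img, (32, 32, 20)) == []

    def test_dc_offset_invariance(self, rng):
        img = np.zeros((96, 96))
        yy, xx = np.mgrid[:96, :96]
        blob = np.exp(-(np.hypot(xx - 48, yy - 48) ** 2) / (2 * 4.0**2))
        img += 50 * blob + 0.05 * rng.standard_normal(img.shape)
        p1 = segment_fluorescence(img, (48, 48, 30))
        p2 = segment_fluorescence(img + 10.0, (48, 48, 30))
        assert len(p1) == len(p2) == 1
        np.testing.assert_array_equal(p1[0].coords, p2[0].coords)
        np.testing.assert_allclose(p1[0].intensities, p2[0].intensities, atol=1e-6)

    def test_generator_clone_jaccard(self, small_colony_config):
        _, fl, gt = synthgen.simulate_colony_stack(small_colony_config)
        f = 12
        cx, cy, R = gt.circles[f]
        patches = segment_fluorescence(fl[f], (cx, cy, R), frame=f)
        assert patches
        found = {tuple(c) for p in patches for c in p.coords}
        truth = {tuple(c) for c in gt.clone_pixels[0][f]["coords"]}
        jac = len(found & truth) / len(found | truth)
        assert jac >= 0.7

    def test_roi_outside_image_rejected(self):
        with pytest.raises(ValueError):
            segment_fluorescence(np.zeros((32, 32)), (100, 100, 5))


class TestNormalizedCoordinates:
    def test_centre_and_plus_x_pixel(self):
        nc = normalize_coordinates(np.array([[50, 50], [50, 70]]), (50.0, 50.0, 20.0))
        assert nc.r_norm[0] == 0.0 and nc.theta[0] == 0.0
        assert nc.r_norm[1] == pytest.approx(1.0)
        assert nc.theta[1] == pytest.approx(0.0)

    def test_y_flip_makes_up_counterclockwise(self):
        # pixel above the centre (smaller row) sits at θ = +π/2
        nc = normalize_coordinates(np.array([[30, 50]]), (50.0, 50.0, 20.0))
        assert nc.theta[0] == pytest.approx(np.pi / 2)

    def test_homothetic_clone_coordinates_are_stationary(self, small_colony_config):
        # purely homothetic motion: no diffusion, no front bias
        cfg = small_colony_config.model_copy(update={"diffusion": 0.0})
        _, _, gt = synthgen.simulate_colony_stack(cfg)
        centroids = []
        for f in range(len(gt.times)):
            rec = gt.clone_pixels[0][f]
            if len(rec["coords"]) == 0:
                continue
            nc = normalize_coordinates(rec["coords"], tuple(gt.circles[f]))
            centroids.append(
                [np.mean(nc.r_norm * np.cos(nc.theta)), np.mean(nc.r_norm * np.sin(nc.theta))]
            )
        drift = np.linalg.norm(np.diff(np.asarray(centroids), axis=0), axis=1)
        assert np.median(drift) < 0.02


class TestCloneAssignment:
    @staticmethod
    def _coords(r, theta):
        from pilisort.colonyimg import NormalizedCoordinates

        return NormalizedCoordinates(r_norm=np.asarray(r), theta=np.asarray(theta))

    def test_two_opposite_clones_separate(self, rng):
        frames = []
        for _ in range(5):
            r1 = np.clip(rng.normal(0.5, 0.05, 40), 0, 1)
            t1 = rng.normal(0.0, 0.1, 40) % (2 * np.pi)
            r2 = np.clip(rng.normal(0.5, 0.05, 40), 0, 1)
            t2 = rng.normal(np.pi, 0.1, 40)
            frames.append(
                self._coords(np.concatenate([r1, r2]), np.concatenate([t1, t2]))
            )
        labels = assign_clones(frames)
        for lab in labels:
            first, second = lab[:40], lab[40:]
            assert len(set(first[first >= 0])) == 1
            assert len(set(second[second >= 0])) == 1
            assert set(first[first >= 0]).isdisjoint(set(second[second >= 0]))

    def test_single_compact_clone_mostly_one_component(self, rng):
        frames = [
            self._coords(
                np.clip(rng.normal(0.4, 0.08, 60), 0, 1), rng.normal(1.0, 0.15, 60)
            )
            for _ in range(4)
        ]
        labels = assign_clones(frames)
        all_lab = np.concatenate(labels)
        main = np.bincount(all_lab[all_lab >= 0]).argmax()
        assert np.mean(all_lab == main) >= 0.95

    def test_manual_whole_disk_polygon_single_label(self):
        frames = [self._coords([0.2, 0.5, 0.9], [0.0, 2.0, 4.0])]
        square = np.array([[-1.1, -1.1], [1.1, -1.1], [1.1, 1.1], [-1.1, 1.1]])
        labels = assign_clones(frames, mode="manual", polygons=[square])
        assert set(labels[0]) == {0}

    def test_no_pixels_empty_labels(self):
        frames = [self._coords(np.empty(0), np.empty(0))]
        assert assign_clones(frames)[0].size == 0
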
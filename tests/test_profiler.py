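"""SAVE profiler: thresholding, geometry, widths, closure, kinetics."""

import numpy as np
import pytest

from conftest import centred_roi, closing_config, tilted_line
from dffoct.errors import DegenerateInputError, InvalidInputError
from dffoct.params import AcquisitionParams, SegmentationParams
from dffoct.profiler import (
    RoiPolygon,
    ScratchLine,
    fit_biexponential,
    interpolate_thresholds,
    multithreshold_first_level,
    rotate_to_vertical,
    run_save_profiler,
    segment_wound,
    width_profile,
    wound_closure,
)
from dffoct.simulate import simulate_wound_timelapse


def between_class_variance_oracle(image, n_classes):
    """Exhaustive search over threshold tuples maximising between-class variance."""
    from itertools import combinations

    vals = np.sort(np.unique(image.ravel()))
    cuts = (vals[1:] + vals[:-1]) / 2
    flat = image.ravel().astype(float)
    best, best_thr = -1.0, None
    for combo in combinations(cuts, n_classes - 1):
        edges = [-np.inf, *combo, np.inf]
        var = 0.0
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = flat[(flat > lo) & (flat <= hi)]
            if sel.size:
                var += sel.size / flat.size * (sel.mean() - flat.mean()) ** 2
        if var > best:
            best, best_thr = var, combo
    return best_thr


class TestMultithreshold:
    def test_binary_image_two_classes(self):
        img = np.zeros((20, 20))
        img[10:] = 255.0
        thr = multithreshold_first_level(img, n_classes=2)
        assert 0 < thr < 255

    def test_three_populations_first_level(self):
        rng = np.random.default_rng(0)
        img = np.concatenate(
            [np.full(300, 10.0), np.full(300, 100.0), np.full(300, 200.0)]
        ) + rng.normal(0, 1, 900)
        img = img.reshape(30, 30)
        thr = multithreshold_first_level(img, n_classes=3)
        assert 10 < thr < 100
        quantised = (img // 8).astype(int) * 8
        t1, _ = between_class_variance_oracle(quantised, 3)
        # any threshold inside the empty 10..100 gap maximises between-class
        # variance equally, so compare the induced class partitions instead
        np.testing.assert_array_equal(quantised < thr, quantised < t1)

    def test_uniform_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            multithreshold_first_level(np.full((10, 10), 3.0), n_classes=3)


class TestInterpolateThresholds:
    @pytest.mark.parametrize(
        "t0, t1, n, expected",
        [
            (10.0, 20.0, 3, [10.0, 15.0, 20.0]),
            (7.0, 7.0, 5, [7.0] * 5),
            (0.0, 1.0, 11, [k / 10 for k in range(11)]),
        ],
    )
    def test_examples(self, t0, t1, n, expected):
        np.testing.assert_allclose(interpolate_thresholds(t0, t1, n), expected)


class TestRotateToVertical:
    def test_vertical_line_is_identity(self):
        stack = np.random.default_rng(0).uniform(size=(3, 20, 20))
        line = ScratchLine((0.0, 10.0), (19.0, 10.0))
        out, angle = rotate_to_vertical(stack, line)
        assert angle == 0.0
        np.testing.assert_array_equal(out, stack)

    def test_diagonal_stripe_becomes_vertical(self):
        n = 101
        rr, cc = np.mgrid[0:n, 0:n]
        img = (np.abs(rr - cc) < 4).astype(float)  # 7 px wide along the diagonal
        line = ScratchLine((10.0, 10.0), (90.0, 90.0))
        rot, angle = rotate_to_vertical(img, line)
        assert abs(abs(angle) - 45.0) < 0.5
        # stripe is now vertical: central rows all have the same width
        rows = (rot > 0.5).sum(axis=1)
        mid = rows[len(rows) // 4 : -len(rows) // 4]
        assert mid.std() < 1.0
        # area preserved: perpendicular width 7/sqrt(2) px over all rows
        expected = 7 / np.sqrt(2) * rot.shape[0]
        assert rot.sum() == pytest.approx(expected, rel=0.02)

    def test_horizontal_line_swaps_axes(self):
        stack = np.ones((2, 40, 80))
        line = ScratchLine((20.0, 0.0), (20.0, 79.0))
        out, angle = rotate_to_vertical(stack, line)
        assert abs(angle) == 90.0
        assert out.shape == (2, 80, 40)

    def test_boolean_frames_stay_boolean(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[:, 20:30] = True
        line = ScratchLine((0.0, 0.0), (49.0, 10.0))
        out, _ = rotate_to_vertical(mask, line)
        assert out.dtype == bool


class TestSegmentWound:
    def setup_method(self):
        self.roi = np.zeros((20, 30), dtype=bool)
        self.roi[2:18, 5:25] = True

    def test_all_above_threshold_gives_empty_mask(self):
        stack = np.full((2, 20, 30), 10.0)
        masks = segment_wound(stack, [5.0, 5.0], self.roi)
        assert not masks.any()

    def test_dark_band_intersection_is_pixel_exact(self):
        stack = np.full((1, 20, 30), 10.0)
        stack[0, :, 12:17] = 1.0
        masks = segment_wound(stack, [5.0], self.roi)
        expected = np.zeros((20, 30), dtype=bool)
        expected[2:18, 12:17] = True
        np.testing.assert_array_equal(masks[0], expected)

    def test_dark_pixels_outside_roi_ignored(self):
        stack = np.full((1, 20, 30), 10.0)
        stack[0, :, 0:3] = 0.0  # dark, but outside the ROI
        masks = segment_wound(stack, [5.0], self.roi)
        assert not masks.any()

    def test_empty_roi_rejected(self):
        with pytest.raises(InvalidInputError):
            segment_wound(np.ones((1, 20, 30)), [0.5], np.zeros((20, 30), bool))

    def test_mask_subset_of_roi(self):
        rng = np.random.default_rng(0)
        stack = rng.uniform(size=(4, 20, 30))
        masks = segment_wound(stack, [0.5] * 4, self.roi)
        assert not (masks & ~self.roi[None]).any()


class TestWoundClosure:
    def test_closing_series(self):
        np.testing.assert_allclose(wound_closure([100.0, 50.0, 0.0]), [0.0, 50.0, 100.0])

    def test_expansion_is_negative(self):
        np.testing.assert_allclose(wound_closure([100.0, 150.0]), [0.0, -50.0])

    def test_zero_initial_area_rejected(self):
        with pytest.raises(InvalidInputError):
            wound_closure([0.0, 10.0])

    def test_matches_pixel_count_oracle_on_simulator_truth(self):
        cfg = closing_config(16.0, 0.0, image_size=128, n_frames=20, wound_angle=0.0)
        _, truth = simulate_wound_timelapse(cfg)
        areas = truth.masks.reshape(len(truth.masks), -1).sum(axis=1).astype(float)
        oracle = (areas[0] - areas) / areas[0] * 100.0
        np.testing.assert_allclose(wound_closure(areas), oracle, rtol=1e-12)


class TestWidthProfile:
    def test_rectangular_wound(self):
        frame = np.zeros((15, 40), dtype=bool)
        frame[:, 10:20] = True
        widths, (lo, mean, hi) = width_profile(frame)
        assert np.all(widths == 10)
        assert (lo, mean, hi) == (10.0, 10.0, 10.0)

    def test_empty_mask(self):
        _, (lo, mean, hi) = width_profile(np.zeros((10, 10), dtype=bool))
        assert (lo, mean, hi) == (0.0, 0.0, 0.0)

    def test_trapezoidal_wound(self):
        n_rows = 9
        frame = np.zeros((n_rows, 40), dtype=bool)
        for r in range(n_rows):
            w = 4 + r  # 4 px top to 12 px bottom
            frame[r, 20 - w // 2 : 20 - w // 2 + w] = True
        _, (lo, mean, hi) = width_profile(frame)
        assert (lo, mean, hi) == (4.0, 8.0, 12.0)


class TestFitBiexponential:
    def test_recovers_known_parameters(self):
        t = np.arange(0.0, 120.0, 1.0)
        w = 10 * np.exp(-0.05 * t) + 2 * np.exp(-0.005 * t)
        fit = fit_biexponential(t, w, closing_limit=0.0)
        terms = sorted([(fit.a, fit.b), (fit.c, fit.d)], key=lambda ab: -ab[0])
        assert terms[0][0] == pytest.approx(10.0, rel=1e-3)
        assert terms[0][1] == pytest.approx(-0.05, rel=1e-3)
        assert terms[1][0] == pytest.approx(2.0, rel=1e-3)
        assert terms[1][1] == pytest.approx(-0.005, rel=1e-3)

    def test_single_exponential_characteristic_time(self):
        tau, w0, limit = 18.0, 7.0, 1.5
        t = np.arange(0.0, 120.0, 1.0)
        w = limit + (w0 - limit) * np.exp(-t / tau)
        fit = fit_biexponential(t, w, closing_limit=limit)
        assert fit.characteristic_time == pytest.approx(tau, rel=0.01)
        assert fit.closed

    def test_constant_width_flags_not_closed(self):
        t = np.arange(0.0, 60.0, 1.0)
        fit = fit_biexponential(t, np.full_like(t, 5.0), closing_limit=1.5)
        assert abs(fit.b) < 1e-4 and abs(fit.d) < 1e-4
        assert fit.average_speed == pytest.approx(0.0, abs=1e-6)
        assert not fit.closed

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_biexponential(np.arange(5.0), np.arange(5.0) + 1, 1.0)

    def test_residual_tracks_noise_level(self):
        rng = np.random.default_rng(9)
        t = np.arange(0.0, 90.0, 1.0)
        sigma = 0.3
        w = 2.0 + 12 * np.exp(-t / 25.0) + rng.normal(0, sigma, t.size)
        fit = fit_biexponential(t, np.clip(w, 0, None), closing_limit=1.5)
        assert fit.residual_rms <= sigma * 1.5


class TestRunSaveProfiler:
    @pytest.mark.parametrize("total_speed, sigma", [(4.0, 0.10), (16.0, 0.10)])
    def test_speed_recovery_under_noise(self, total_speed, sigma):
        cfg = closing_config(total_speed, sigma, pixel_size=0.5)
        stack, truth = simulate_wound_timelapse(cfg)
        res = run_save_profiler(
            stack,
            tilted_line(cfg.image_size, cfg.wound_angle),
            centred_roi(cfg.image_size, 25 / cfg.pixel_size / 2 + 10),
            AcquisitionParams(pixel_size=cfg.pixel_size),
            SegmentationParams(n_classes=4),
        )
        assert res.fit.average_speed == pytest.approx(truth.closure_speed_um_h, rel=0.10)

    def test_area_equals_mask_pixel_count(self, closing_stack_8, acquisition_1um):
        cfg, stack, _ = closing_stack_8
        res = run_save_profiler(
            stack,
            tilted_line(cfg.image_size, cfg.wound_angle),
            centred_roi(cfg.image_size, 23),
            acquisition_1um,
            SegmentationParams(n_classes=4),
        )
        assert np.all(res.trace.area_px == res.trace.area_px.astype(int))
        np.testing.assert_allclose(
            res.trace.area_um2, res.trace.area_px * cfg.pixel_size**2
        )
        # width summaries are ordered
        assert np.all(res.trace.width_min_um <= res.trace.width_mean_um + 1e-9)
        assert np.all(res.trace.width_mean_um <= res.trace.width_max_um + 1e-9)
        assert res.trace.closure_pct[0] == 0.0

    def test_closure_invariant_under_intensity_rescale(self, closing_stack_8, acquisition_1um):
        cfg, stack, _ = closing_stack_8
        line = tilted_line(cfg.image_size, cfg.wound_angle)
        roi = centred_roi(cfg.image_size, 23)
        seg = SegmentationParams(n_classes=4)
        res_a = run_save_profiler(stack, line, roi, acquisition_1um, seg)
        res_b = run_save_profiler(stack * 2.5, line, roi, acquisition_1um, seg)
        np.testing.assert_allclose(
            res_a.trace.closure_pct, res_b.trace.closure_pct, atol=1.0
        )

    def test_static_wound_closure_stays_near_zero(self):
        cfg = closing_config(
            16.0, 0.05, image_size=128, n_frames=20,
            border_speeds=(0.0, 0.0), initial_width=12.0, pixel_size=0.5,
        )
        stack, _ = simulate_wound_timelapse(cfg)
        res = run_save_profiler(
            stack,
            tilted_line(128, cfg.wound_angle),
            centred_roi(128, 12 / 0.5 / 2 + 8),
            AcquisitionParams(pixel_size=0.5),
            SegmentationParams(n_classes=4),
        )
        assert np.all(np.abs(res.trace.closure_pct) < 5.0)

    def test_expanding_wound_goes_negative(self):
        cfg = closing_config(
            8.0, 0.02, image_size=128, n_frames=30, scenario="expand",
            initial_width=10.0, pixel_size=0.5, border_speeds=(4.0, 4.0),
        )
        stack, _ = simulate_wound_timelapse(cfg)
        res = run_save_profiler(
            stack,
            tilted_line(128, cfg.wound_angle),
            centred_roi(128, 30),
            AcquisitionParams(pixel_size=0.5),
            SegmentationParams(n_classes=4),
        )
        closure = res.trace.closure_pct
        assert closure[-1] < -20.0
        # monotone non-increasing trend once expansion is underway
        smoothed = np.convolve(closure, np.ones(5) / 5, mode="valid")
        assert np.all(np.diff(smoothed) < 1.0)


class TestRoiPolygon:
    def test_self_intersecting_polygon_rejected(self):
        with pytest.raises(InvalidInputError):
            RoiPolygon([(0.0, 0.0), (10.0, 10.0), (0.0, 10.0), (10.0, 0.0)])

    def test_degenerate_line_rejected(self):
        with pytest.raises(InvalidInputError):
            ScratchLine((3.0, 4.0), (3.0, 4.0))
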
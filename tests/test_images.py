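"""Image pipeline: shading correction, masking, ROI extraction."""

import math

import numpy as np
import pytest

from phagedrop import (
    CircularROI,
    FrameStack,
    OpticsParams,
    ShadingFieldSpec,
    apply_shading_correction,
    background_mask,
    build_shading_corrector,
    extract_trajectories,
    mean_roi_intensity,
    subtract_background,
)
from phagedrop.images import ShadingCorrector, flag_out_of_focus, roi_pixel_mask
from phagedrop.render import place_cells, render_frame


def brute_force_roi_mean(frame, roi):
    """Independent per-pixel enumeration of the inclusive-disc ROI mean."""
    total = 0.0
    n = 0
    for y in range(frame.shape[0]):
        for x in range(frame.shape[1]):
            if (x - roi.cx) ** 2 + (y - roi.cy) ** 2 <= roi.r**2:
                total += frame[y, x]
                n += 1
    return total / n, n


class TestShadingCorrector:
    def test_identical_frames_normalized_by_median(self, rng):
        frame = rng.uniform(10, 100, (16, 16))
        corr = build_shading_corrector(np.stack([frame] * 4))
        np.testing.assert_allclose(corr.image, frame / np.median(frame))

    def test_uniform_frames_give_unit_corrector(self):
        corr = build_shading_corrector(np.full((3, 8, 8), 7.0))
        np.testing.assert_allclose(corr.image, 1.0)

    def test_median_projection_rejects_single_artifact(self, rng):
        """One frame corrupted by a bright artifact does not change the
        corrector: the pixel-wise median ignores a single outlier."""
        clean = rng.uniform(50, 60, (12, 12))
        stack = np.stack([clean] * 5)
        corrupted = stack.copy()
        corrupted[2, 3:6, 3:6] = 1e4
        np.testing.assert_allclose(
            build_shading_corrector(corrupted).image,
            build_shading_corrector(stack).image,
        )

    def test_normalization_idempotent(self, rng):
        frame = rng.uniform(1, 5, (10, 10))
        once = build_shading_corrector(frame[None])
        twice = build_shading_corrector(once.image[None])
        np.testing.assert_allclose(once.image, twice.image)
        assert np.median(once.image) == pytest.approx(1.0)

    def test_degenerate_flatfield_refused(self):
        with pytest.raises(ValueError, match="median"):
            build_shading_corrector(np.zeros((2, 4, 4)))


class TestApplyCorrection:
    def test_recovers_constant_from_scaled_field(self, rng):
        corr = ShadingCorrector(rng.uniform(0.5, 1.5, (8, 8)))
        np.testing.assert_allclose(
            apply_shading_correction(3.5 * corr.image, corr), 3.5
        )

    def test_unit_corrector_is_identity(self, rng):
        frame = rng.uniform(0, 10, (8, 8))
        corr = ShadingCorrector(np.ones((8, 8)))
        np.testing.assert_array_equal(apply_shading_correction(frame, corr), frame)

    def test_shape_mismatch_rejected(self):
        corr = ShadingCorrector(np.ones((8, 8)))
        with pytest.raises(ValueError, match="shape"):
            apply_shading_correction(np.ones((4, 4)), corr)

    def test_round_trip_through_renderer(self, rng):
        """Correcting a rendered frame with a corrector built from the true
        shading field recovers the unshaded render up to a global scale."""
        optics = OpticsParams(
            image_size_px=(128, 128),
            droplet_centers_um=((41.6, 41.6),),
            shading=ShadingFieldSpec(amplitude=0.35),
            defocus_fraction=0.0,
        )
        flat_optics = OpticsParams(
            image_size_px=(128, 128),
            droplet_centers_um=((41.6, 41.6),),
            shading=ShadingFieldSpec(amplitude=0.0),
            defocus_fraction=0.0,
        )
        pts = place_cells(25, optics, np.random.default_rng(3))
        shaded = render_frame(pts, optics, np.random.default_rng(4))
        unshaded = render_frame(pts, flat_optics, np.random.default_rng(4))
        from phagedrop.render import shading_field

        corr = build_shading_corrector(shading_field(optics)[None])
        recovered = apply_shading_correction(shaded, corr)
        scale = np.median(shading_field(optics))
        np.testing.assert_allclose(recovered, scale * unshaded, rtol=1e-9)


class TestBackgroundMask:
    def test_fixed_threshold_selects_cell_pixels(self):
        frame = np.full((10, 10), 10.0)
        frame[4:6, 4:6] = 100.0
        mask = background_mask(frame, strategy="fixed", threshold=50.0)
        assert mask.sum() == 4
        assert np.all(mask[4:6, 4:6] == 1)

    def test_threshold_above_max_gives_empty_mask(self):
        frame = np.random.default_rng(0).uniform(0, 10, (10, 10))
        assert background_mask(frame, "fixed", threshold=20.0).sum() == 0

    def test_otsu_on_constant_frame_refused(self):
        with pytest.raises(ValueError, match="constant"):
            background_mask(np.full((8, 8), 3.0), strategy="otsu")

    def test_otsu_recall_on_rendered_cells(self):
        """Otsu recovers at least 95% of in-focus cell pixels (ground truth:
        pixels inside a kernel's full width at half maximum) on a synthetic
        frame."""
        optics = OpticsParams(
            image_size_px=(128, 128),
            droplet_centers_um=((41.6, 41.6),),
            shading=ShadingFieldSpec(amplitude=0.0),
            defocus_fraction=0.0,
            background_level=20.0,
        )
        pts = place_cells(30, optics, np.random.default_rng(5))
        frame = render_frame(pts, optics, np.random.default_rng(6))
        cells_only = frame - optics.background_level
        peak = optics.cell_intensity / (
            2 * np.pi * (optics.cell_sigma_um / optics.pixel_size_um) ** 2
        )
        truth = cells_only > 0.5 * peak
        mask = background_mask(frame, strategy="otsu").astype(bool)
        recall = (mask & truth).sum() / truth.sum()
        assert recall >= 0.95


class TestSubtractBackground:
    def test_all_ones_mask_is_identity(self, rng):
        frame = rng.uniform(0, 5, (6, 6))
        np.testing.assert_array_equal(
            subtract_background(frame, np.ones((6, 6))), frame
        )

    def test_zero_mask_zeroes_frame(self, rng):
        frame = rng.uniform(0, 5, (6, 6))
        assert subtract_background(frame, np.zeros((6, 6))).sum() == 0

    def test_background_region_exactly_zero(self):
        frame = np.full((10, 10), 10.0)
        frame[4:6, 4:6] = 100.0
        mask = background_mask(frame, "fixed", threshold=50.0)
        cleaned = subtract_background(frame, mask)
        assert cleaned[mask == 0].sum() == 0.0


class TestRoiMean:
    def test_constant_frame(self):
        roi = CircularROI(cx=8, cy=8, r=5)
        assert mean_roi_intensity(np.full((17, 17), 4.25), roi) == pytest.approx(4.25)

    def test_single_bright_pixel_divided_by_pixel_count(self):
        frame = np.zeros((21, 21))
        frame[10, 10] = 77.0
        roi = CircularROI(cx=10, cy=10, r=4.5)
        _, n = brute_force_roi_mean(frame, roi)
        assert mean_roi_intensity(frame, roi) == pytest.approx(77.0 / n)

    def test_zeroed_region_gives_zero(self):
        assert mean_roi_intensity(np.zeros((17, 17)), CircularROI(8, 8, 5)) == 0.0

    def test_matches_brute_force_enumeration(self, rng):
        """Vectorized disc membership and mean agree exactly with a
        per-pixel enumeration oracle on random integer frames."""
        for _ in range(25):
            h, w = rng.integers(9, 30, 2)
            frame = rng.integers(0, 1000, (h, w)).astype(float)
            r = rng.uniform(1.0, min(h, w) / 2 - 1)
            cx = rng.uniform(r, w - 1 - r)
            cy = rng.uniform(r, h - 1 - r)
            roi = CircularROI(cx=cx, cy=cy, r=r)
            expected, _ = brute_force_roi_mean(frame, roi)
            assert mean_roi_intensity(frame, roi) == expected

    def test_roi_outside_image_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            mean_roi_intensity(np.zeros((10, 10)), CircularROI(1, 1, 5))

    def test_roi_covering_no_pixel_center_rejected(self):
        with pytest.raises(ValueError, match="no pixel"):
            mean_roi_intensity(np.zeros((10, 10)), CircularROI(4.5, 4.5, 0.4))


class TestExtractTrajectories:
    def _stack_and_tools(self):
        frames = np.stack([np.full((16, 16), 5.0 * (k + 1)) for k in range(4)])
        stack = FrameStack(frames=frames, dt_min=3.0, t0_min=12.0,
                           excluded_frames={1})
        corr = ShadingCorrector(np.ones((16, 16)))
        roi = CircularROI(cx=8, cy=8, r=4, id="d0")
        return stack, corr, roi

    def test_times_and_exclusions_propagate(self):
        stack, corr, roi = self._stack_and_tools()
        (traj,) = extract_trajectories(stack, corr, [roi], strategy="fixed",
                                       threshold=1.0)
        np.testing.assert_allclose(traj.times, [12.0, 15.0, 18.0, 21.0])
        assert traj.excluded == frozenset({1})

    def test_all_frames_excluded_all_points_flagged(self):
        stack, corr, roi = self._stack_and_tools()
        stack.excluded_frames = frozenset(range(4))
        (traj,) = extract_trajectories(stack, corr, [roi], strategy="fixed",
                                       threshold=1.0)
        assert traj.excluded == frozenset(range(4))

    def test_identical_rois_identical_series(self):
        stack, corr, roi = self._stack_and_tools()
        roi2 = CircularROI(cx=roi.cx, cy=roi.cy, r=roi.r, id="d1")
        t1, t2 = extract_trajectories(stack, corr, [roi, roi2],
                                      strategy="fixed", threshold=1.0)
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_empty_stack_rejected(self):
        _, corr, roi = self._stack_and_tools()
        stack = FrameStack(frames=np.empty((0, 16, 16)), dt_min=3.0)
        with pytest.raises(ValueError, match="empty"):
            extract_trajectories(stack, corr, [roi], strategy="fixed", threshold=1.0)

    def test_linearity_in_cell_brightness(self):
        """With a fixed mask, doubling every cell's brightness doubles the
        background-subtracted ROI mean within 1%."""
        base = OpticsParams(
            image_size_px=(128, 128),
            droplet_centers_um=((41.6, 41.6),),
            shading=ShadingFieldSpec(amplitude=0.0),
            defocus_fraction=0.0,
            background_level=0.0,
        )
        bright = OpticsParams(
            image_size_px=(128, 128),
            droplet_centers_um=((41.6, 41.6),),
            shading=ShadingFieldSpec(amplitude=0.0),
            defocus_fraction=0.0,
            background_level=0.0,
            cell_intensity=2 * base.cell_intensity,
        )
        pts = place_cells(20, base, np.random.default_rng(8))
        roi = CircularROI(cx=64, cy=64, r=52)
        frame_base = render_frame(pts, base, np.random.default_rng(9))
        frame_bright = render_frame(pts, bright, np.random.default_rng(9))
        mask = background_mask(frame_base, "fixed", threshold=0.5)
        v_base = mean_roi_intensity(subtract_background(frame_base, mask), roi)
        v_bright = mean_roi_intensity(subtract_background(frame_bright, mask), roi)
        assert v_bright == pytest.approx(2 * v_base, rel=0.01)


class TestFocusFlagging:
    def test_blurred_frames_flagged(self, rng):
        sharp = rng.uniform(0, 100, (32, 32))
        from scipy import ndimage

        blurred = ndimage.gaussian_filter(sharp, 3.0)
        frames = np.stack([sharp, sharp, blurred, sharp, sharp])
        stack = FrameStack(frames=frames, dt_min=3.0)
        assert flag_out_of_focus(stack, fraction=0.5) == frozenset({2})


class TestRoiMaskConvention:
    def test_inclusive_boundary_pixel_membership(self):
        """A pixel center exactly on the circle boundary is included."""
        mask = roi_pixel_mask(CircularROI(cx=5, cy=5, r=2), (11, 11))
        assert mask[5, 7] and mask[7, 5] and not mask[7, 7]
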
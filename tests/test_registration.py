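"""Vessel-boundary detection and percentage registration error."""

import numpy as np
import pytest

from cdqa.errors import LumenNotFoundError, NoFlowError
from cdqa.io import Rect, RegionLayout
from cdqa.phantom import PhantomSpec, simulate_bmode
from cdqa.preprocess import AverageImage, saturation_mask
from cdqa.registration import (
    VesselBoundaries,
    detect_vessel_boundaries,
    estimate_registration_error,
)

from conftest import averages


def tiny_layout(h=30, w=30):
    return RegionLayout(
        diagnostic_box=Rect(0, h, 0, w),
        color_box=Rect(2, h - 2, 2, w - 2),
    )


def color_avg(colored_pixels, shape=(30, 30)):
    """Average image with pure-red color at the given (row, col) pixels."""
    rgb = np.zeros(shape + (3,), dtype=float)
    for r, c in colored_pixels:
        rgb[r, c] = (200.0, 20.0, 0.0)
    return AverageImage(rgb=rgb, mask=saturation_mask(rgb, 0.35), index=1)


def flat_bounds(upper_row, lower_row):
    return VesselBoundaries(
        upper_line=(0.0, float(upper_row)),
        lower_line=(0.0, float(lower_row)),
        th_b=0.3,
        lumen_mask=np.zeros((30, 30), bool),
    )


class TestDetectVesselBoundaries:
    def test_horizontal_vessel_slopes_zero(self, bmode_image):
        img, gt = bmode_image
        bounds = detect_vessel_boundaries(img, gt.layout, c_b=0.5)
        assert bounds.upper_line[0] == pytest.approx(0.0, abs=0.02)
        assert bounds.lower_line[0] == pytest.approx(0.0, abs=0.02)
        assert bounds.upper_line[1] == pytest.approx(gt.upper_line[1], abs=1.5)
        assert bounds.lower_line[1] == pytest.approx(gt.lower_line[1], abs=1.5)

    def test_slanted_vessel_slope_recovered(self):
        spec = PhantomSpec(
            vessel_depth_mm=25.0, vessel_angle_deg=8.0, fov_cm=10.0, image_shape=(320, 400)
        )
        img, gt = simulate_bmode(spec, seed=21)
        bounds = detect_vessel_boundaries(img, gt.layout, c_b=0.5)
        true_slope = gt.upper_line[0]
        assert bounds.upper_line[0] == pytest.approx(true_slope, abs=0.02)
        assert bounds.lower_line[0] == pytest.approx(true_slope, abs=0.02)

    def test_uniform_bright_image_errors(self):
        layout = tiny_layout()
        img = np.full((30, 30, 3), 200, dtype=np.uint8)
        with pytest.raises(LumenNotFoundError):
            detect_vessel_boundaries(img, layout, c_b=0.5)

    def test_lower_line_below_upper(self, bmode_image):
        img, gt = bmode_image
        bounds = detect_vessel_boundaries(img, gt.layout, c_b=0.5)
        cols = np.arange(gt.layout.color_box.c0, gt.layout.color_box.c1)
        up = bounds.upper_line[0] * cols + bounds.upper_line[1]
        lo = bounds.lower_line[0] * cols + bounds.lower_line[1]
        assert (lo > up).all()


class TestEstimateRegistrationError:
    def test_all_inside_gives_zero(self):
        avg = color_avg([(r, c) for r in range(12, 18) for c in range(5, 25)])
        res = estimate_registration_error([avg], flat_bounds(10, 20), tiny_layout())
        assert res.RE_pct == 0.0

    def test_known_fraction(self):
        inside = [(15, c) for c in range(3, 28)] * 3  # rows 14..16 handled below
        inside = [(r, c) for r in (14, 15, 16) for c in range(3, 28)]  # 75 px inside
        outside = [(5, c) for c in range(3, 28)]  # 25 px above the upper line
        avg = color_avg(inside + outside)
        res = estimate_registration_error([avg], flat_bounds(10, 20), tiny_layout())
        assert res.RE_pct == pytest.approx(25.0)
        assert res.counts[0] == (25, 100)

    def test_pixel_on_boundary_counts_inside(self):
        avg = color_avg([(10, 15), (20, 15), (15, 15)])
        res = estimate_registration_error([avg], flat_bounds(10, 20), tiny_layout())
        assert res.RE_pct == 0.0

    def test_no_flow_error(self):
        avg = color_avg([])
        with pytest.raises(NoFlowError):
            estimate_registration_error([avg], flat_bounds(10, 20), tiny_layout())

    def test_widening_lines_decreases_re(self):
        pixels = [(r, 15) for r in range(5, 26)]
        avg = color_avg(pixels)
        narrow = estimate_registration_error([avg], flat_bounds(13, 17), tiny_layout())
        wide = estimate_registration_error([avg], flat_bounds(8, 22), tiny_layout())
        assert wide.RE_pct < narrow.RE_pct

    def test_recolor_above_threshold_invariant(self):
        pixels = [(r, c) for r in (8, 15, 22) for c in range(5, 25)]
        avg1 = color_avg(pixels)
        rgb2 = np.zeros((30, 30, 3))
        for r, c in pixels:
            rgb2[r, c] = (0.0, 30.0, 220.0)  # different hue, still saturated
        avg2 = AverageImage(rgb=rgb2, mask=saturation_mask(rgb2, 0.35), index=1)
        bounds, layout = flat_bounds(10, 20), tiny_layout()
        assert (
            estimate_registration_error([avg1], bounds, layout).RE_pct
            == estimate_registration_error([avg2], bounds, layout).RE_pct
        )

    def test_bleed_scene_matches_bruteforce_fraction(self, bleed_video, bmode_image):
        stack, gt = bleed_video
        bimg, _ = bmode_image
        bounds = detect_vessel_boundaries(bimg, gt.layout, c_b=0.5)
        avgs = averages(stack)
        res = estimate_registration_error(avgs, bounds, gt.layout)
        # brute-force oracle from the generator's ground truth masks
        from cdqa.preprocess import intensity_map

        imap = intensity_map(avgs[0])
        cb = gt.layout.color_box.mask(imap.I.shape)
        above = (imap.I > 10.0) & cb
        n_out_true = int((above & gt.bleed_mask).sum())
        n_box_true = int(above.sum())
        expected = 100.0 * n_out_true / n_box_true
        assert res.RE_pct == pytest.approx(expected, abs=1.0)

    def test_zero_bleed_scene_scores_zero(self, clean_video, bmode_image):
        stack, gt = clean_video
        bimg, _ = bmode_image
        bounds = detect_vessel_boundaries(bimg, gt.layout, c_b=0.5)
        res = estimate_registration_error(averages(stack), bounds, gt.layout)
        assert res.RE_pct == pytest.approx(0.0, abs=0.5)
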
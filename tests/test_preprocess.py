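"""Saturation masking, frame averaging, median denoising, intensity map."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from cdqa.errors import ParameterError, PartitionError
from cdqa.io import AcquisitionMeta, FrameStack
from cdqa.preprocess import (
    AverageImage,
    intensity_map,
    make_average_images,
    median_denoise,
    saturation,
    saturation_mask,
)

rgb_images = hnp.arrays(
    dtype=np.uint8, shape=st.tuples(st.integers(4, 12), st.integers(4, 12), st.just(3))
)


def stack_of(arrays):
    return FrameStack(
        frames=[np.asarray(a, dtype=np.uint8) for a in arrays],
        frame_period=0.1,
        meta=AcquisitionMeta(),
    )


class TestSaturationMask:
    @pytest.mark.parametrize(
        "pixel, expected_s, included",
        [
            ((128, 128, 128), 0.0, False),  # gray: zero saturation
            ((255, 0, 0), 1.0, True),  # pure red
            ((200, 150, 150), 0.25, False),  # 50/200 below the 0.35 default
        ],
    )
    def test_hexcone_formula(self, pixel, expected_s, included):
        img = np.array([[pixel]], dtype=np.uint8)
        assert saturation(img)[0, 0] == pytest.approx(expected_s)
        assert bool(saturation_mask(img, 0.35).mask[0, 0]) is included

    def test_black_pixel_defined(self):
        assert saturation(np.zeros((1, 1, 3), np.uint8))[0, 0] == 0.0

    def test_threshold_bounds(self):
        with pytest.raises(ParameterError):
            saturation_mask(np.zeros((2, 2, 3), np.uint8), 1.5)

    @settings(max_examples=25, deadline=None)
    @given(img=rgb_images, th=st.floats(0.0, 0.9))
    def test_monotone_in_threshold(self, img, th):
        low = saturation_mask(img, th).mask
        high = saturation_mask(img, min(th + 0.1, 1.0)).mask
        assert not np.any(high & ~low)  # raising th never adds pixels


class TestAverageImages:
    def test_consecutive_partition(self):
        frames = [np.full((4, 4, 3), 5 * i, dtype=np.uint8) for i in range(30)]
        avgs = make_average_images(stack_of(frames), N=6, M=5)
        assert len(avgs) == 6
        # image i averages frames (i-1)*M+1 .. i*M (1-based)
        for i, avg in enumerate(avgs):
            expected = np.mean([5 * j for j in range(i * 5, (i + 1) * 5)])
            assert avg.rgb[0, 0, 0] == pytest.approx(expected)
            assert avg.index == i + 1

    def test_identical_frames_idempotent(self):
        frame = np.random.default_rng(3).integers(0, 255, (5, 5, 3), dtype=np.uint8)
        avgs = make_average_images(stack_of([frame] * 12), N=6, M=2)
        for avg in avgs:
            np.testing.assert_allclose(avg.rgb, frame.astype(float))

    def test_two_frame_mean(self):
        a = np.zeros((2, 2, 3), np.uint8)
        b = np.full((2, 2, 3), 250, np.uint8)
        (avg,) = make_average_images(stack_of([a, b]), N=1, M=2)
        assert avg.rgb[0, 0, 0] == pytest.approx(125.0)

    def test_partition_error(self):
        with pytest.raises(PartitionError):
            make_average_images(stack_of([np.zeros((2, 2, 3), np.uint8)] * 10), N=6, M=2)

    def test_repeated_indices_rejected(self):
        frames = [np.zeros((2, 2, 3), np.uint8)] * 6
        with pytest.raises(PartitionError):
            make_average_images(stack_of(frames), N=2, M=2, groups=[[0, 1], [1, 2]])

    def test_explicit_groups_cover_distinct_frames(self):
        frames = [np.full((2, 2, 3), i, dtype=np.uint8) for i in range(8)]
        groups = [[7, 0], [3, 4], [1, 6]]
        avgs = make_average_images(stack_of(frames), N=3, M=2, groups=groups)
        for avg, g in zip(avgs, groups):
            assert avg.rgb[0, 0, 0] == pytest.approx(np.mean(g))


def brute_force_median(img, k):
    """Per-pixel lower median over k x k, edge-replicated borders."""
    pad = k // 2
    padded = np.pad(img, pad, mode="edge")
    out = np.empty_like(img, dtype=float)
    rank = (k * k - 1) // 2
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            win = padded[r : r + k, c : c + k]
            out[r, c] = np.sort(win, axis=None)[rank]
    return out


class TestMedianDenoise:
    def _avg(self, arr):
        arr = np.asarray(arr, dtype=float)
        return AverageImage(rgb=arr, mask=saturation_mask(arr, 0.35), index=1)

    def test_constant_unchanged(self):
        avg = self._avg(np.full((6, 6, 3), 77.0))
        out = median_denoise(avg, 4)
        np.testing.assert_allclose(out.rgb, avg.rgb)

    def test_hot_pixel_removed(self):
        img = np.zeros((8, 8, 3))
        img[4, 4] = 255.0
        out = median_denoise(self._avg(img), 4)
        assert out.rgb.max() == 0.0

    @pytest.mark.parametrize("k", [3, 4])
    def test_matches_bruteforce_oracle(self, k):
        rng = np.random.default_rng(7)
        img = rng.integers(0, 255, (8, 8, 3)).astype(float)
        out = median_denoise(self._avg(img), k)
        for ch in range(3):
            np.testing.assert_allclose(out.rgb[..., ch], brute_force_median(img[..., ch], k))

    def test_oversized_kernel_rejected(self):
        with pytest.raises(ParameterError):
            median_denoise(self._avg(np.zeros((4, 4, 3))), 9)


class TestIntensityMap:
    @pytest.mark.parametrize(
        "pixel, expected",
        [((0, 0, 0), 0.0), ((255, 255, 255), 255.0), ((128, 0, 0), 73.9)],
    )
    def test_rms_formula(self, pixel, expected):
        arr = np.array([[pixel]], dtype=float)
        avg = AverageImage(rgb=arr, mask=saturation_mask(arr, 0.0), index=1)
        avg.mask.mask[:] = True  # isolate the formula from the mask
        assert intensity_map(avg).I[0, 0] == pytest.approx(expected, abs=0.05)

    def test_masked_pixels_zeroed(self):
        arr = np.full((2, 2, 3), 200.0)
        avg = AverageImage(rgb=arr, mask=saturation_mask(arr, 0.35), index=1)
        assert intensity_map(avg).I.max() == 0.0  # gray pixels fail the mask

    @settings(max_examples=20, deadline=None)
    @given(img=rgb_images)
    def test_channel_permutation_invariant(self, img):
        arr = img.astype(float)
        avg1 = AverageImage(rgb=arr, mask=saturation_mask(arr, 0.35), index=1)
        avg2 = AverageImage(rgb=arr[..., ::-1], mask=saturation_mask(arr[..., ::-1], 0.35), index=1)
        np.testing.assert_allclose(intensity_map(avg1).I, intensity_map(avg2).I)
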
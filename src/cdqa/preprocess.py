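"""Color-pixel extraction, frame averaging and the shared intensity map.

Every estimator that counts pixels starts from the same preprocessing
chain: color-coded pixels are isolated with a threshold on HSV saturation
(gray B-mode echoes have near-zero saturation, Doppler colors are highly
saturated), the video is condensed into N average images of M consecutive
frames each, color noise is suppressed with a small median filter, and the
RGB content is collapsed into a single gray-level intensity map that can be
compared against the "blind" threshold th_blind (the smallest gray-level
difference distinguishable by eye, 10 on the 0-255 scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError, PartitionError
from .io import FrameStack, RegionLayout

__all__ = [
    "ColorMask",
    "AverageImage",
    "IntensityMap",
    "saturation",
    "saturation_mask",
    "extract_color",
    "make_average_images",
    "median_denoise",
    "intensity_map",
    "DEFAULT_TH_SAT",
    "DEFAULT_TH_BLIND",
]

DEFAULT_TH_SAT = 0.35
DEFAULT_TH_BLIND = 10.0


@dataclass(frozen=True)
class ColorMask:
    mask: np.ndarray  # boolean, H x W
    th_sat: float


@dataclass
class AverageImage:
    """Mean of M distinct video frames, with its color mask."""

    rgb: np.ndarray  # float, H x W x 3
    mask: ColorMask
    index: int = 0  # 1-based position in the N-image sequence


@dataclass
class IntensityMap:
    """Gray-level intensity (0-255) of the color-coded content."""

    I: np.ndarray  # float, H x W
    th_blind: float = DEFAULT_TH_BLIND


def saturation(image: np.ndarray) -> np.ndarray:
    """Per-pixel HSV (hexcone) saturation S = (max - min) / max, S=0 at black."""
    rgb = np.asarray(image, dtype=float)
    mx = rgb.max(axis=-1)
    mn = rgb.min(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(mx > 0, (mx - mn) / np.where(mx > 0, mx, 1.0), 0.0)
    return s


def saturation_mask(
    image: np.ndarray,
    th_sat: float = DEFAULT_TH_SAT,
    color_box: RegionLayout | None = None,
) -> ColorMask:
    """Select color-coded pixels: saturation strictly above ``th_sat``.

    When a layout is given the mask is additionally restricted to the color
    box, where Doppler data can legitimately appear.
    """
    if not 0.0 <= th_sat <= 1.0:
        raise ParameterError("th_sat must be in [0, 1]")
    m = saturation(image) > th_sat
    if color_box is not None:
        m &= color_box.color_box.mask(np.asarray(image).shape)
    return ColorMask(mask=m, th_sat=th_sat)


def extract_color(image: np.ndarray, th_sat: float = DEFAULT_TH_SAT) -> np.ndarray:
    """Zero every pixel whose saturation is at or below ``th_sat``.

    The Doppler processing chains run the saturation filter on each video
    frame *before* averaging, so grayscale B-mode content (including the
    dark lumen speckle inside a blind zone) never leaks into the averaged
    color data.
    """
    out = np.asarray(image, dtype=float).copy()
    out[~(saturation(out) > th_sat)] = 0.0
    return out


def make_average_images(
    stack: FrameStack,
    N: int,
    M: int,
    th_sat: float = DEFAULT_TH_SAT,
    consecutive: bool = True,
    groups: list[list[int]] | None = None,
    color_only: bool = False,
) -> list[AverageImage]:
    """Average M consecutive frames into each of N average images.

    Image i (1-based) averages frames (i-1)*M .. i*M-1 when ``consecutive``;
    an explicit ``groups`` list of frame-index groups overrides the
    partition (used by the Monte-Carlo frame resampling, which randomizes
    group membership without repetition).  With ``color_only`` each frame
    is passed through :func:`extract_color` first, as the estimator
    pipelines do; the plain per-channel mean is the default.  The color
    mask of each average image is computed from the averaged RGB.
    """
    if N < 1 or M < 1:
        raise ParameterError("N and M must be >= 1")
    if N * M > stack.n_fr:
        raise PartitionError(f"N*M = {N * M} exceeds the {stack.n_fr} frames available")
    if groups is None:
        if not consecutive:
            raise ParameterError("non-consecutive averaging requires explicit groups")
        groups = [list(range(i * M, (i + 1) * M)) for i in range(N)]
    if len(groups) != N or any(len(g) != M for g in groups):
        raise PartitionError("groups must be N lists of M frame indices")
    flat = [j for g in groups for j in g]
    if len(set(flat)) != len(flat):
        raise PartitionError("frame indices must not repeat across groups")

    out = []
    for i, g in enumerate(groups, start=1):
        frames = (
            [extract_color(stack.frames[j], th_sat) for j in g]
            if color_only
            else [np.asarray(stack.frames[j], dtype=float) for j in g]
        )
        avg = np.mean(frames, axis=0)
        out.append(AverageImage(rgb=avg, mask=saturation_mask(avg, th_sat), index=i))
    return out


def median_denoise(avg: AverageImage, k: int = 4) -> AverageImage:
    """Median-filter each channel over a k-by-k window to suppress color noise.

    Even windows use the lower median (rank (k*k-1)//2); borders replicate
    the edge pixel.  The color mask is recomputed on the filtered image.
    """
    if k < 1:
        raise ParameterError("kernel size must be >= 1")
    h, w = avg.rgb.shape[:2]
    if k > min(h, w):
        raise ParameterError(f"kernel {k} larger than image {h}x{w}")
    rank = (k * k - 1) // 2
    filtered = np.stack(
        [
            ndimage.rank_filter(avg.rgb[..., c], rank=rank, size=k, mode="nearest")
            for c in range(avg.rgb.shape[-1])
        ],
        axis=-1,
    )
    return AverageImage(
        rgb=filtered,
        mask=saturation_mask(filtered, avg.mask.th_sat),
        index=avg.index,
    )


def intensity_map(avg: AverageImage, th_blind: float = DEFAULT_TH_BLIND) -> IntensityMap:
    """Collapse RGB to one gray level: the RMS of the three channels.

    I = sqrt((R^2 + G^2 + B^2) / 3) stays on the 0-255 scale (white maps to
    255) so it is directly comparable with th_blind.  Pixels outside the
    color mask are set to 0.
    """
    rgb = np.asarray(avg.rgb, dtype=float)
    I = np.sqrt(np.mean(rgb**2, axis=-1))
    I[~avg.mask.mask] = 0.0
    return IntensityMap(I=I, th_blind=th_blind)
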
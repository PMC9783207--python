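"""Blind-angle estimation from a horizontal-vessel Color Doppler video.

Around 90 degrees of insonation the Doppler shift vanishes and the system
displays a black gap in the middle of an otherwise colored vessel.  The
width ``a`` of that gap at depth ``h`` subtends the blind angle

    alpha = 2 * arctan(a / (2 h)),

the angular range over which the probe cannot detect flow.  The estimator
measures ``a`` along F parallel flow axes (the fitted vessel centerline and
copies offset by +-d along its normal), repeats the measurement on each of
the N average images, and aggregates:

    BA       = mean_i(alpha_i)
    sigma_BA = (1/N) * sqrt(sum_i sigma_alpha_i^2)

where alpha_i and sigma_alpha_i are the mean and SD over the F axes of
average image i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, NoFlowError
from .io import PixelCalibration, RegionLayout
from .preprocess import (
    DEFAULT_TH_BLIND,
    AverageImage,
    IntensityMap,
    intensity_map,
    median_denoise,
)

__all__ = [
    "FlowAxisSet",
    "BlindAngleResult",
    "BlindAngleSettings",
    "fit_central_axis",
    "detect_flow_axes",
    "blind_zone_length",
    "estimate_blind_angle",
]


@dataclass(frozen=True)
class BlindAngleSettings:
    """Method settings: defaults follow the protocol's variable table."""

    th_sat: float = 0.35
    N: int = 6
    M: int | None = None  # defaults to n_fr // N
    k: int = 4
    F: int = 3
    d_mm: float = 1.0
    th_blind: float = DEFAULT_TH_BLIND


@dataclass
class FlowAxisSet:
    """F parallel flow axes, as (rows, cols) polylines over the color region."""

    F: int
    d_mm: float
    axes: list[tuple[np.ndarray, np.ndarray]]  # [(rows, cols), ...]
    slope: float  # fitted centerline slope, rows per column
    intercept: float


@dataclass
class BlindAngleResult:
    BA: float  # degrees
    sigma_BA: float  # degrees
    per_image: list[tuple[float, float]] = field(default_factory=list)  # (alpha_i, sd_i)
    a_mm: list[list[float]] = field(default_factory=list)  # per image, per axis
    h_mm: float = float("nan")


def fit_central_axis(imap: IntensityMap) -> tuple[float, float, int, int]:
    """Least-squares line through the per-column centroid of the color region.

    Returns (slope, intercept, c_min, c_max): row = slope*col + intercept,
    valid over the closed column span [c_min, c_max] of the color region.
    """
    I = imap.I
    cols_any = np.flatnonzero((I > 0).any(axis=0))
    if cols_any.size == 0:
        raise NoFlowError("intensity map contains no color pixels")
    rows_idx = np.arange(I.shape[0], dtype=float)
    centroids = []
    for c in cols_any:
        w = I[:, c] > 0
        centroids.append(rows_idx[w].mean())
    centroids = np.asarray(centroids)
    if cols_any.size >= 2:
        slope, intercept = np.polyfit(cols_any.astype(float), centroids, 1)
    else:
        slope, intercept = 0.0, centroids[0]
    return float(slope), float(intercept), int(cols_any[0]), int(cols_any[-1])


def detect_flow_axes(
    imap: IntensityMap,
    calib: PixelCalibration,
    F: int = 3,
    d_mm: float = 1.0,
) -> FlowAxisSet:
    """Place F parallel flow axes spaced d mm apart across the vessel.

    The central axis is the least-squares centerline of the color region;
    the remaining F-1 axes are offset by multiples of +-d along the vessel
    normal.  Axes are rasterized one pixel per column over the full column
    span of the color region so that interior gaps (blind zones) are
    crossed, not skipped.
    """
    slope, intercept, c0, c1 = fit_central_axis(imap)
    cols = np.arange(c0, c1 + 1)
    # A line parallel at perpendicular distance delta has its intercept
    # shifted by delta * sqrt(1 + slope^2).
    d_px = d_mm / calib.mm_per_px_axial
    shift = math.sqrt(1.0 + slope * slope)
    offsets = [(j - (F - 1) / 2.0) for j in range(F)] if F > 1 else [0.0]
    axes = []
    for off in offsets:
        b = intercept + off * d_px * shift
        rows = np.rint(slope * cols + b).astype(int)
        axes.append((rows, cols.copy()))
    return FlowAxisSet(F=F, d_mm=d_mm, axes=axes, slope=slope, intercept=intercept)


def blind_zone_length(
    imap: IntensityMap,
    axis: tuple[np.ndarray, np.ndarray],
    th_blind: float,
    calib: PixelCalibration,
    color_box: RegionLayout | None = None,
) -> float:
    """Transversal size ``a`` (mm) of the blind zone along one flow axis.

    ``a`` is the longest contiguous run of axis pixels with intensity
    <= th_blind that is flanked on *both* sides by axis pixels above the
    threshold; gaps touching the color-box edge are absence of color box,
    not absence of signal, and are not counted.  Ties between equally long
    runs are broken in favor of the run nearest the lateral box center.
    Returns 0 when no interior gap exists.
    """
    rows, cols = axis
    h, w = imap.I.shape
    inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    if color_box is not None:
        cb = color_box.color_box
        inside &= (rows >= cb.r0) & (rows < cb.r1) & (cols >= cb.c0) & (cols < cb.c1)
    if not inside.any():
        raise GeometryError("flow axis lies entirely outside the color box")
    rows, cols = rows[inside], cols[inside]
    vals = imap.I[rows, cols]
    below = vals <= th_blind

    center_c = (cols[0] + cols[-1]) / 2.0
    if color_box is not None:
        center_c = (color_box.color_box.c0 + color_box.color_box.c1 - 1) / 2.0

    best_len, best_dist = 0, math.inf
    n = below.size
    i = 0
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            # interior run only: flanked by above-threshold pixels
            if i > 0 and j < n:
                length = j - i
                mid = (cols[i] + cols[j - 1]) / 2.0
                dist = abs(mid - center_c)
                if length > best_len or (length == best_len and dist < best_dist):
                    best_len, best_dist = length, dist
            i = j
        else:
            i += 1
    return best_len * calib.mm_per_px_lateral


def estimate_blind_angle(
    avgs: list[AverageImage],
    layout: RegionLayout,
    calib: PixelCalibration,
    settings: BlindAngleSettings | None = None,
) -> BlindAngleResult:
    """Run the blind-angle pipeline on the N average images.

    Each average image is median-filtered, collapsed to an intensity map,
    and scanned along F parallel axes; alpha = 2*arctan(a / 2h) with h the
    depth (mm) of the axis midpoint below the scan surface.
    """
    settings = settings or BlindAngleSettings()
    per_image: list[tuple[float, float]] = []
    a_all: list[list[float]] = []
    h_mm = float("nan")
    for avg in avgs:
        den = median_denoise(avg, settings.k)
        imap = intensity_map(den, settings.th_blind)
        axset = detect_flow_axes(imap, calib, settings.F, settings.d_mm)
        alphas, a_img = [], []
        for rows, cols in axset.axes:
            a = blind_zone_length(imap, (rows, cols), settings.th_blind, calib, layout)
            mid_row = rows[len(rows) // 2]
            h_mm = (mid_row - layout.scan_surface_row) * calib.mm_per_px_axial
            if h_mm <= 0:
                raise GeometryError("flow axis above the scan surface")
            alphas.append(math.degrees(2.0 * math.atan2(a, 2.0 * h_mm)))
            a_img.append(a)
        alphas = np.asarray(alphas)
        sd = float(alphas.std(ddof=1)) if alphas.size > 1 else 0.0
        per_image.append((float(alphas.mean()), sd))
        a_all.append(a_img)

    N = len(per_image)
    BA = float(np.mean([m for m, _ in per_image]))
    sigma = float(np.sqrt(np.sum([s**2 for _, s in per_image])) / N)
    return BlindAngleResult(BA=BA, sigma_BA=sigma, per_image=per_image, a_mm=a_all, h_mm=h_mm)
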
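"""Color-to-velocity conversion and the two velocity QA parameters.

The displayed color encodes the axial velocity through the on-screen
colorbar.  Sampling the colorbar strip gives a lookup from RGB to velocity;
a linear regression of velocity against the dominant channel of each limb
provides the calibration residual sigma_cal that is carried into the
velocity uncertainties.

Two parameters are derived from velocity profiles reconstructed along K
segments drawn perpendicular to the vessel axis over a central distance D:

* AMVS (average maximum velocity sensitivity): the measured change in peak
  velocity between two flow rates divided by the theoretical change,
  AMVS = dv_color / dv_th.  Ideal value 1.
* VeMeA (velocity measurements accuracy): relative deviation of the
  measured mean velocity from the phantom's theoretical mean velocity,
  VeMeA = |v_color_mean - v_th_mean| / v_th_mean.  Ideal value 0.

Theoretical velocities come from the phantom's volumetric flow rate Q and
vessel diameter: mean = Q / (pi r^2), peak = profile_factor * mean with
profile_factor = 2 for fully developed laminar (parabolic) flow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, DegenerateInputError, GeometryError, NoFlowError
from .io import PixelCalibration, RegionLayout
from .preprocess import AverageImage, IntensityMap, intensity_map
from .blind_angle import fit_central_axis

__all__ = [
    "ColorbarCalibration",
    "SegmentSet",
    "VelocityEstimate",
    "AmvsResult",
    "VemeaResult",
    "VelocitySettings",
    "calibrate_colorbar",
    "pixel_to_velocity",
    "place_segments",
    "profile_stat",
    "theoretical_flow_velocity",
    "estimate_velocity",
    "estimate_amvs",
    "estimate_vemea",
]

#: Phantom tolerances: flow meter +-0.4 mL/s, vessel inner diameter +-0.2 mm.
FLOW_RATE_SD = 0.4
DIAMETER_SD = 0.2
VESSEL_DIAMETER_MM = 5.0


@dataclass(frozen=True)
class VelocitySettings:
    th_sat: float = 0.35
    N: int = 6
    M: int | None = None
    K: int = 16
    D_mm: float = 20.0
    center_offset_mm: float = 0.0  # shift of the segment block along the axis
    match_tolerance: float = 60.0  # max RGB distance for a colorbar match


@dataclass
class ColorbarCalibration:
    """Sampled colorbar colors with their velocities and linear limb fits."""

    colors: np.ndarray  # n x 3 float
    velocities: np.ndarray  # n, cm/s
    positions: np.ndarray  # n, row indices along the strip
    sigma_cal: float  # residual SD of the limb regressions, cm/s
    endpoints: tuple[float, float]  # (top, bottom) cm/s
    match_tolerance: float = 60.0


@dataclass
class SegmentSet:
    K: int
    D_mm: float
    segments: list[tuple[np.ndarray, np.ndarray]]  # [(rows, cols), ...]


@dataclass
class VelocityEstimate:
    value: float  # cm/s
    sd: float  # cm/s, across-image SD combined with sigma_cal
    mode: str  # "peak" or "mean"
    per_image: list[float] = field(default_factory=list)


@dataclass
class AmvsResult:
    AMVS: float
    sigma_AMVS: float
    v_color: tuple[float, float]  # (Q1, Q2) measured
    v_th: tuple[float, float]


@dataclass
class VemeaResult:
    VeMeA: float
    sigma_VeMeA: float
    v_color: float
    v_th: float


def calibrate_colorbar(frame: np.ndarray, layout: RegionLayout) -> ColorbarCalibration:
    """Sample the on-screen colorbar and build the color-to-velocity lookup.

    Colors are read along the vertical midline of the colorbar strip; the
    velocity at each row is linear between the configured endpoint
    velocities.  Each limb (positive / negative velocities) is regressed
    linearly, velocity against its dominant color channel, and the pooled
    residual SD becomes sigma_cal.
    """
    if layout.colorbar_strip is None or layout.colorbar_velocities is None:
        raise CalibrationError("layout carries no colorbar strip / velocity endpoints")
    strip = layout.colorbar_strip
    if strip.height < 2 or strip.width < 1:
        raise CalibrationError("colorbar strip must be at least 2 px tall")
    v_top, v_bottom = layout.colorbar_velocities

    mid_c = (strip.c0 + strip.c1 - 1) // 2
    rows = np.arange(strip.r0, strip.r1)
    colors = np.asarray(frame, dtype=float)[rows, mid_c, :3]
    t = (rows - strip.r0) / (strip.height - 1)
    velocities = v_top + (v_bottom - v_top) * t

    residuals = []
    for limb in (velocities > 0, velocities < 0):
        if np.count_nonzero(limb) >= 2:
            dom = colors[limb].max(axis=1)  # dominant channel brightness
            if np.ptp(dom) > 0:
                coef = np.polyfit(dom, velocities[limb], 1)
                residuals.append(velocities[limb] - np.polyval(coef, dom))
                order = np.argsort(np.abs(velocities[limb]))
                if np.any(np.diff(dom[order]) < 0):
                    warnings.warn("colorbar limb is not monotone in its dominant channel")
    sigma_cal = float(np.std(np.concatenate(residuals))) if residuals else 0.0
    return ColorbarCalibration(
        colors=colors,
        velocities=velocities,
        positions=rows.astype(float),
        sigma_cal=sigma_cal,
        endpoints=(float(v_top), float(v_bottom)),
    )


def pixel_to_velocity(rgb: np.ndarray, cal: ColorbarCalibration) -> float:
    """Decode one pixel: velocity of the nearest colorbar color (RGB distance).

    Returns NaN when no colorbar color lies within the match tolerance
    (e.g. gray B-mode pixels that slipped through the saturation mask).
    """
    v = decode_velocities(np.asarray(rgb, dtype=float)[None, :], cal)[0]
    return float(v)


def decode_velocities(rgb: np.ndarray, cal: ColorbarCalibration) -> np.ndarray:
    """Vectorized nearest-color decoding of an (n, 3) pixel array."""
    pix = np.asarray(rgb, dtype=float)
    d2 = ((pix[:, None, :] - cal.colors[None, :, :]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)
    out = cal.velocities[idx].astype(float).copy()
    bad = np.sqrt(d2[np.arange(pix.shape[0]), idx]) > cal.match_tolerance
    out[bad] = np.nan
    return out


def place_segments(
    imap: IntensityMap,
    calib: PixelCalibration,
    K: int = 16,
    D_mm: float = 20.0,
    half_length_px: int | None = None,
    center_offset_mm: float = 0.0,
) -> SegmentSet:
    """Draw K segments perpendicular to the central flow axis.

    The segments are evenly spaced over an arc distance D centered at the
    axis midpoint, and each spans the vessel cross-section (half-length
    defaults to the color-region height).  Requires the colored axis to be
    at least D long.
    """
    if K < 2:
        raise GeometryError("need at least K = 2 segments")
    slope, intercept, c0, c1 = fit_central_axis(imap)
    step_mm = calib.mm_per_px_lateral * math.sqrt(1.0 + slope * slope)
    length_mm = (c1 - c0) * step_mm
    if length_mm < D_mm:
        raise GeometryError(f"flow axis ({length_mm:.1f} mm) shorter than D = {D_mm} mm")

    if half_length_px is None:
        rows_any = np.flatnonzero((imap.I > 0).any(axis=1))
        half_length_px = int((rows_any[-1] - rows_any[0]) / 2) + 2

    mid_c = (c0 + c1) / 2.0 + center_offset_mm / step_mm
    span_px = D_mm / step_mm  # columns covered by D along the axis
    centers_c = mid_c + np.linspace(-span_px / 2.0, span_px / 2.0, K)
    # unit normal to the axis direction (1, slope)/|.|
    norm = math.sqrt(1.0 + slope * slope)
    n_c, n_r = -slope / norm, 1.0 / norm
    t = np.arange(-half_length_px, half_length_px + 1, dtype=float)

    segments = []
    h, w = imap.I.shape
    for cc in centers_c:
        rc = slope * cc + intercept
        rows = np.rint(rc + t * n_r).astype(int)
        cols = np.rint(cc + t * n_c).astype(int)
        ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        segments.append((rows[ok], cols[ok]))
    return SegmentSet(K=K, D_mm=D_mm, segments=segments)


def profile_stat(
    avg: AverageImage,
    segment: tuple[np.ndarray, np.ndarray],
    cal: ColorbarCalibration,
    mode: str = "peak",
) -> float | None:
    """Peak or mean |velocity| of the profile reconstructed along one segment.

    Only color-mask pixels with a valid colorbar match contribute; segments
    with fewer than 3 valid samples are skipped (returns None).
    """
    rows, cols = segment
    valid = avg.mask.mask[rows, cols]
    if np.count_nonzero(valid) < 3:
        return None
    pix = avg.rgb[rows[valid], cols[valid], :3]
    v = decode_velocities(pix, cal)
    v = np.abs(v[np.isfinite(v)])
    if v.size < 3:
        return None
    return float(v.max() if mode == "peak" else v.mean())


def theoretical_flow_velocity(
    Q: float,
    diameter_mm: float = VESSEL_DIAMETER_MM,
    mode: str = "mean",
    profile_factor: float = 2.0,
    sigma_Q: float = FLOW_RATE_SD,
    sigma_d: float = DIAMETER_SD,
) -> tuple[float, float]:
    """Theoretical phantom velocity (cm/s) with its SD.

    mean = Q / (pi r^2); peak = profile_factor * mean (2.0 for parabolic,
    fully developed laminar flow).  The SD propagates the phantom
    tolerances on Q and on the vessel diameter (v ~ Q d^-2).
    """
    if Q <= 0 or diameter_mm <= 0:
        raise DegenerateInputError("flow rate and diameter must be positive")
    r_cm = diameter_mm / 20.0
    v_mean = Q / (math.pi * r_cm**2)
    v = v_mean if mode == "mean" else profile_factor * v_mean
    rel = math.sqrt((sigma_Q / Q) ** 2 + (2.0 * sigma_d / diameter_mm) ** 2)
    return v, v * rel


def estimate_velocity(
    avgs: list[AverageImage],
    cal: ColorbarCalibration,
    calib: PixelCalibration,
    mode: str = "peak",
    settings: VelocitySettings | None = None,
) -> VelocityEstimate:
    """Aggregate segment velocities over the N average images.

    Per image: the mean of the K segment statistics, with an SD that
    combines the across-segment SD with sigma_cal by root-sum-square.  The
    overall value is the mean over images; its SD follows the propagation
    law sd = (1/N) sqrt(sum_i sd_i^2).
    """
    settings = settings or VelocitySettings()
    per_image, per_sd = [], []
    for avg in avgs:
        imap = intensity_map(avg)
        segset = place_segments(
            imap, calib, settings.K, settings.D_mm,
            center_offset_mm=settings.center_offset_mm,
        )
        stats = [profile_stat(avg, seg, cal, mode) for seg in segset.segments]
        stats = np.asarray([s for s in stats if s is not None])
        if stats.size == 0:
            raise NoFlowError(f"average image {avg.index}: no usable segments")
        seg_sd = float(stats.std(ddof=1)) if stats.size > 1 else 0.0
        per_image.append(float(stats.mean()))
        per_sd.append(math.hypot(seg_sd, cal.sigma_cal))
    N = len(per_image)
    value = float(np.mean(per_image))
    sd = float(np.sqrt(np.sum(np.square(per_sd))) / N)
    return VelocityEstimate(value=value, sd=sd, mode=mode, per_image=per_image)


def estimate_amvs(
    v1: VelocityEstimate,
    v2: VelocityEstimate,
    vth1: tuple[float, float],
    vth2: tuple[float, float],
) -> AmvsResult:
    """AMVS = dv_color / dv_th with first-order uncertainty propagation.

    The SDs of the two measured (theoretical) velocities combine by
    root-sum-square into the SD of each difference.
    """
    dv_color = v2.value - v1.value
    dv_th = vth2[0] - vth1[0]
    if dv_th == 0:
        raise DegenerateInputError("theoretical velocities are equal (Q1 == Q2?)")
    amvs = dv_color / dv_th
    s_dc = math.hypot(v1.sd, v2.sd)
    s_dt = math.hypot(vth1[1], vth2[1])
    if dv_color == 0:
        sigma = abs(s_dc / dv_th)  # limit of the propagation law at AMVS = 0
    else:
        sigma = abs(amvs) * math.sqrt((s_dc / dv_color) ** 2 + (s_dt / dv_th) ** 2)
    return AmvsResult(
        AMVS=amvs,
        sigma_AMVS=sigma,
        v_color=(v1.value, v2.value),
        v_th=(vth1[0], vth2[0]),
    )


def estimate_vemea(
    vbar: VelocityEstimate,
    vth: tuple[float, float],
) -> VemeaResult:
    """VeMeA = |v_color_mean - v_th_mean| / v_th_mean with propagated SD."""
    v_th, s_th = vth
    if v_th <= 0:
        raise DegenerateInputError("theoretical mean velocity must be positive")
    vemea = abs(vbar.value - v_th) / v_th
    rel_c = vbar.sd / vbar.value if vbar.value != 0 else 0.0
    sigma = vemea * math.sqrt(rel_c**2 + (s_th / v_th) ** 2)
    return VemeaResult(VeMeA=vemea, sigma_VeMeA=sigma, v_color=vbar.value, v_th=v_th)
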
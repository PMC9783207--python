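"""Synthetic Doppler flow-phantom frame generator with exact ground truth.

Real QA acquisitions come from a commercial flow phantom: a straight
vessel of 5.0 mm inner diameter filled with blood-mimicking fluid at a
constant, adjustable flow rate (1.7-12.5 mL/s), imaged as B-mode stills
and short duplex Color Doppler videos.  No such recordings can ship with a
software package, so this module renders the same scene class directly:

* a bright multiplicative-speckle background with a dark (anechoic) lumen
  band at a known depth and angle,
* a constant laminar flow whose per-pixel velocity follows either a
  parabolic profile v(r) = profile_factor * v_mean * (1 - (r/R)^2) or a
  uniform (plug) profile, encoded through a two-limb linear colormap (red
  toward the probe, blue away) with known velocity endpoints, plus the
  matching on-screen colorbar strip,
* controllable artifacts: a blind zone (color suppressed near 90 degrees
  insonation), color bleeding outside the walls, per-frame color noise and
  color dropout.

Rendering is rectilinear (linear-probe geometry) so the ground truth -
wall lines, velocity field, blind-zone extent, bleed mask - is exact by
construction.  Everything is driven by an explicit seed; identical specs
and seed give bit-identical frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .errors import SpecError
from .io import (
    AcquisitionMeta,
    FrameStack,
    PixelCalibration,
    Rect,
    RegionLayout,
    calibrate_pixels,
    extract_us_image,
    layout_to_dict,
)

__all__ = [
    "PhantomSpec",
    "FlowSpec",
    "ArtifactSpec",
    "GroundTruth",
    "encode_velocity",
    "simulate_bmode",
    "simulate_cd_video",
    "write_fixture",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Virtual phantom scene: vessel geometry and display layout."""

    vessel_diameter_mm: float = 5.0
    vessel_depth_mm: float = 20.0  # depth of the vessel axis below the scan surface
    vessel_angle_deg: float = 0.0  # 0 = horizontal vessel; 40 = diagonal vessel
    fov_cm: float = 5.0
    image_shape: tuple[int, int] = (480, 640)
    fr_duplex: float = 10.0
    fr_bmode: float = 40.0


@dataclass(frozen=True)
class FlowSpec:
    """Constant-flow regime; velocities derive from Q and the vessel area."""

    Q: float = 6.0  # mL/s, within the phantom's 1.7-12.5 range
    profile_factor: float = 2.0  # peak/mean ratio; 2.0 = parabolic laminar flow
    profile: str = "parabolic"  # or "uniform" (plug flow at v_mean)
    nyquist: float | None = None  # cm/s scale endpoint; None = auto (no aliasing)
    direction: int = 1  # +1 toward the probe (red), -1 away (blue)

    def __post_init__(self) -> None:
        if not 1.7 <= self.Q <= 12.5:
            raise SpecError(f"flow rate {self.Q} outside the phantom range 1.7-12.5 mL/s")
        if self.profile not in ("parabolic", "uniform"):
            raise SpecError("profile must be 'parabolic' or 'uniform'")


@dataclass(frozen=True)
class ArtifactSpec:
    blind_zone_width_mm: float = 0.0
    bleed_rate: float = 0.0  # probability of coloring a pixel in the bleed band
    bleed_band_mm: float = 1.5  # radial extent of the band outside the walls
    color_noise_sd: float = 0.0  # RGB units, per frame
    frame_jitter: float = 0.0  # per-frame color dropout probability

    def __post_init__(self) -> None:
        for p in (self.bleed_rate, self.frame_jitter):
            if not 0.0 <= p <= 1.0:
                raise SpecError("probabilities must be in [0, 1]")


@dataclass
class GroundTruth:
    layout: RegionLayout
    calib: PixelCalibration
    upper_line: tuple[float, float]  # row = slope*col + intercept
    lower_line: tuple[float, float]
    lumen_mask: np.ndarray
    velocity: np.ndarray | None = None  # cm/s per pixel (signed), colored region only
    blind_zone_width_mm: float = 0.0
    bleed_mask: np.ndarray | None = None
    colored_mask: np.ndarray | None = None  # in-vessel colored pixels (per average frame)
    v_mean: float = 0.0  # cm/s, Q / A
    v_peak: float = 0.0  # cm/s, rendered centerline peak
    nyquist: float = 0.0
    fr_duplex: float = 0.0
    fr_bmode: float = 0.0
    meta: AcquisitionMeta | None = None


# ---------------------------------------------------------------------------
# color encoding


def encode_velocity(v: np.ndarray, nyquist: float) -> np.ndarray:
    """Two-limb linear colormap: red limb for v > 0, blue limb for v < 0.

    |v|/nyquist = t maps to a dominant channel 60 + 195 t with a weak
    green admixture 45 t; v = 0 maps to black.  Saturation is 1 for any
    colored pixel, so the standard saturation mask recovers exactly the
    flow region.
    """
    v = np.asarray(v, dtype=float)
    t = np.clip(np.abs(v) / nyquist, 0.0, 1.0)
    dom = np.where(t > 0, 60.0 + 195.0 * t, 0.0)
    grn = 45.0 * t
    rgb = np.zeros(v.shape + (3,))
    pos = v > 0
    neg = v < 0
    rgb[..., 0] = np.where(pos, dom, 0.0)
    rgb[..., 2] = np.where(neg, dom, 0.0)
    rgb[..., 1] = np.where(pos | neg, grn, 0.0)
    return np.rint(rgb).astype(np.uint8)


def _colorbar_strip(strip: Rect, nyquist: float) -> np.ndarray:
    rows = np.arange(strip.height)
    t = rows / (strip.height - 1)
    v = nyquist * (1.0 - 2.0 * t)  # +nyquist at the top, -nyquist at the bottom
    col = encode_velocity(v, nyquist)
    return np.repeat(col[:, None, :], strip.width, axis=1)


# ---------------------------------------------------------------------------
# scene geometry


def _default_layout(spec: PhantomSpec, nyquist: float) -> tuple[RegionLayout, PixelCalibration]:
    h, w = spec.image_shape
    diag = Rect(20, h - 20, 30, w - 80)
    strip_h = max(64, min(220, h - 120))
    strip = Rect(40, 40 + strip_h, w - 60, w - 40)
    layout = RegionLayout(
        diagnostic_box=diag,
        color_box=diag,  # placeholder; replaced below
        colorbar_strip=strip,
        colorbar_velocities=(nyquist, -nyquist),
        scan_surface_row=diag.r0,
    )
    calib = calibrate_pixels(layout, spec.fov_cm)
    # color box: generous band around the vessel, inset from the box sides
    m = np.tan(np.deg2rad(spec.vessel_angle_deg))
    c0, c1 = diag.c0 + 40, diag.c1 - 40
    center0 = diag.r0 + spec.vessel_depth_mm / calib.mm_per_px_axial
    mid_c = (diag.c0 + diag.c1) / 2.0
    rad_px = spec.vessel_diameter_mm / 2.0 / calib.mm_per_px_axial
    rows_at = [center0 + m * (c - mid_c) for c in (c0, c1)]
    r0 = int(min(rows_at) - 3.0 * rad_px)
    r1 = int(max(rows_at) + 3.0 * rad_px)
    r0 = max(r0, diag.r0 + 2)
    r1 = min(r1, diag.r1 - 2)
    if r1 - r0 < 4 * rad_px:
        raise SpecError("vessel does not fit within the field of view")
    layout = RegionLayout(
        diagnostic_box=diag,
        color_box=Rect(r0, r1, c0, c1),
        colorbar_strip=strip,
        colorbar_velocities=(nyquist, -nyquist),
        scan_surface_row=diag.r0,
    )
    return layout, calib


def _vessel_geometry(spec: PhantomSpec, layout: RegionLayout, calib: PixelCalibration):
    """Signed perpendicular distance (mm) of every pixel from the vessel axis."""
    h, w = spec.image_shape
    m = np.tan(np.deg2rad(spec.vessel_angle_deg))
    diag = layout.diagnostic_box
    mid_c = (diag.c0 + diag.c1) / 2.0
    intercept = diag.r0 + spec.vessel_depth_mm / calib.mm_per_px_axial - m * mid_c
    rr, cc = np.mgrid[0:h, 0:w]
    # distance from line row = m*col + b, in px then mm (isotropic pixels)
    dist_px = (rr - (m * cc + intercept)) / np.sqrt(1.0 + m * m)
    dist_mm = dist_px * calib.mm_per_px_axial
    radius_px = spec.vessel_diameter_mm / 2.0 / calib.mm_per_px_axial
    shift = radius_px * np.sqrt(1.0 + m * m)
    upper = (m, intercept - shift)
    lower = (m, intercept + shift)
    return dist_mm, (m, intercept), upper, lower


def simulate_bmode(
    spec: PhantomSpec, seed: int = 0
) -> tuple[np.ndarray, GroundTruth]:
    """Render a masked B-mode still: speckle background, dark lumen band."""
    rng = np.random.default_rng(seed)
    layout, calib = _default_layout(spec, nyquist=50.0)
    dist_mm, _, upper, lower = _vessel_geometry(spec, layout, calib)
    lumen = np.abs(dist_mm) <= spec.vessel_diameter_mm / 2.0

    h, w = spec.image_shape
    speckle = rng.gamma(shape=4.0, scale=0.25, size=(h, w))  # mean 1, multiplicative
    gray = np.where(lumen, 10.0 * speckle, 170.0 * speckle)
    img = np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    img = np.repeat(img[..., None], 3, axis=2)
    img = extract_us_image(img, layout)

    gt = GroundTruth(
        layout=layout,
        calib=calib,
        upper_line=upper,
        lower_line=lower,
        lumen_mask=lumen & layout.diagnostic_box.mask((h, w)),
        fr_duplex=spec.fr_duplex,
        fr_bmode=spec.fr_bmode,
        meta=AcquisitionMeta(fov_cm=spec.fov_cm, fr_duplex=spec.fr_duplex,
                             fr_bmode=spec.fr_bmode, layout=layout),
    )
    return img, gt


def simulate_cd_video(
    spec: PhantomSpec,
    flow: FlowSpec,
    artifacts: ArtifactSpec | None = None,
    n_fr: int = 30,
    seed: int = 0,
    probe_model: str = "phased",
) -> tuple[FrameStack, GroundTruth]:
    """Render a duplex Color Doppler frame stack with exact ground truth.

    The per-pixel velocity is the signed in-plane flow speed: parabolic
    profile_factor * (Q/A) * (1 - (r/R)^2) across the lumen, or a uniform
    plug at Q/A.  Colors follow the two-limb map with the configured (or
    auto-chosen) velocity scale; the generator refuses scales that would
    alias.  Artifacts are applied in order: blind zone (color removed in a
    band around the color-box center), bleeding (static colored pixels in a
    ring outside the walls), per-frame color noise and dropout.
    """
    artifacts = artifacts or ArtifactSpec()
    rng = np.random.default_rng(seed)

    radius_mm = spec.vessel_diameter_mm / 2.0
    v_mean = flow.Q / (np.pi * (radius_mm / 10.0) ** 2)  # cm/s
    v_peak = v_mean if flow.profile == "uniform" else flow.profile_factor * v_mean
    nyquist = flow.nyquist if flow.nyquist is not None else float(np.ceil(1.15 * v_peak))
    if v_peak > nyquist:
        raise SpecError(
            f"rendered peak {v_peak:.1f} cm/s exceeds the {nyquist:.1f} cm/s scale (aliasing)"
        )

    layout, calib = _default_layout(spec, nyquist)
    dist_mm, _, upper, lower = _vessel_geometry(spec, layout, calib)
    h, w = spec.image_shape
    inside = np.abs(dist_mm) <= radius_mm

    if flow.profile == "uniform":
        vfield = np.where(inside, flow.direction * v_mean, 0.0)
    else:
        vfield = np.where(
            inside,
            flow.direction * flow.profile_factor * v_mean * (1.0 - (dist_mm / radius_mm) ** 2),
            0.0,
        )

    cbox_mask = layout.color_box.mask((h, w))
    colored = inside & cbox_mask

    # blind zone: suppress color in a column band centered on the color box
    blind_cols = np.zeros(w, dtype=bool)
    if artifacts.blind_zone_width_mm > 0:
        half_px = artifacts.blind_zone_width_mm / 2.0 / calib.mm_per_px_lateral
        cc = (layout.color_box.c0 + layout.color_box.c1 - 1) / 2.0
        cols = np.arange(w)
        blind_cols = np.abs(cols - cc) <= half_px
        colored &= ~blind_cols[None, :]

    # bleeding: static colored pixels in a ring just outside the walls
    bleed_mask = np.zeros((h, w), dtype=bool)
    if artifacts.bleed_rate > 0:
        gap_px = 1.5  # keep clear of the rasterized wall so truth is unambiguous
        band = (
            (np.abs(dist_mm) > radius_mm + gap_px * calib.mm_per_px_axial)
            & (np.abs(dist_mm) <= radius_mm + gap_px * calib.mm_per_px_axial
               + artifacts.bleed_band_mm)
            & cbox_mask
        )
        bleed_mask = band & (rng.random((h, w)) < artifacts.bleed_rate)

    # base scene (static): B-mode background + lumen + color overlay + colorbar
    speckle = rng.gamma(shape=4.0, scale=0.25, size=(h, w))
    gray = np.where(np.abs(dist_mm) <= radius_mm, 10.0 * speckle, 170.0 * speckle)
    base = np.repeat(np.clip(np.rint(gray), 0, 255).astype(np.uint8)[..., None], 3, axis=2)

    color_rgb = encode_velocity(vfield, nyquist)
    bleed_speed = 0.25 * nyquist * flow.direction  # slow-flow colored speckle
    bleed_rgb = encode_velocity(np.full((h, w), bleed_speed), nyquist)

    scene = base.copy()
    scene[colored] = color_rgb[colored]
    scene[bleed_mask] = bleed_rgb[bleed_mask]
    if layout.colorbar_strip is not None:
        scene[layout.colorbar_strip.slices()] = _colorbar_strip(layout.colorbar_strip, nyquist)

    frames = []
    color_any = colored | bleed_mask
    for _ in range(n_fr):
        f = scene.astype(float)
        if artifacts.frame_jitter > 0:
            drop = color_any & (rng.random((h, w)) < artifacts.frame_jitter)
            f[drop] = base[drop]
        if artifacts.color_noise_sd > 0:
            noise = rng.normal(0.0, artifacts.color_noise_sd, size=(h, w, 3))
            f[color_any] += noise[color_any]
        frames.append(np.clip(np.rint(f), 0, 255).astype(np.uint8))

    meta = AcquisitionMeta(
        probe_model=probe_model,
        fov_cm=spec.fov_cm,
        fr_duplex=spec.fr_duplex,
        fr_bmode=spec.fr_bmode,
        flow_rate=flow.Q,
        layout=layout,
    )
    stack = FrameStack(frames=frames, frame_period=1.0 / spec.fr_duplex, meta=meta)
    gt = GroundTruth(
        layout=layout,
        calib=calib,
        upper_line=upper,
        lower_line=lower,
        lumen_mask=inside,
        velocity=vfield,
        blind_zone_width_mm=artifacts.blind_zone_width_mm,
        bleed_mask=bleed_mask,
        colored_mask=colored,
        v_mean=float(v_mean),
        v_peak=float(v_peak),
        nyquist=float(nyquist),
        fr_duplex=spec.fr_duplex,
        fr_bmode=spec.fr_bmode,
        meta=meta,
    )
    return stack, gt


def write_fixture(
    stack: FrameStack, gt: GroundTruth, out_dir: str | Path
) -> dict[str, str]:
    """Write PNG frames + metadata YAML + ground-truth JSON; round-trips
    through :func:`cdqa.io.load_frames` / :func:`cdqa.io.load_meta`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(stack.frames):
        iio.imwrite(out / f"frame_{i:03d}.png", frame)

    meta = stack.meta
    meta_d = {
        "probe_model": meta.probe_model,
        "configuration": meta.configuration,
        "fov_cm": meta.fov_cm,
        "fr_duplex": meta.fr_duplex,
        "fr_bmode": meta.fr_bmode,
        "flow_rate": meta.flow_rate,
        "layout": layout_to_dict(gt.layout),
    }
    (out / "meta.yaml").write_text(yaml.safe_dump(meta_d, sort_keys=True))

    gt_d = {
        "upper_line": list(gt.upper_line),
        "lower_line": list(gt.lower_line),
        "blind_zone_width_mm": gt.blind_zone_width_mm,
        "v_mean_cm_s": gt.v_mean,
        "v_peak_cm_s": gt.v_peak,
        "nyquist_cm_s": gt.nyquist,
        "fr_duplex": gt.fr_duplex,
        "fr_bmode": gt.fr_bmode,
        "n_bleed_pixels": int(gt.bleed_mask.sum()) if gt.bleed_mask is not None else 0,
        "mm_per_px_axial": gt.calib.mm_per_px_axial,
        "mm_per_px_lateral": gt.calib.mm_per_px_lateral,
    }
    (out / "ground_truth.json").write_text(json.dumps(gt_d, indent=1))
    return {"frames": str(out), "meta": str(out / "meta.yaml"),
            "ground_truth": str(out / "ground_truth.json")}
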
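"""Frame loading, display-region masking, and pixel calibration.

Color Doppler quality-control acquisitions are exported as short duplex
videos (color flow superimposed on B-mode) plus still B-mode images.  The
vendor display contains overlays (patient banner, settings, colorbar) that
must be excluded before any pixel counting; the diagnostic box, color box
and colorbar strip are therefore declared explicitly in a
:class:`RegionLayout` and applied by :func:`extract_us_image`.

Coordinates are 0-based, row-major, origin at the top-left; depth increases
with the row index.  Rectangles are half-open ``[r0, r1) x [c0, c1)``.
"""

from __future__ import annotations

import glob as _glob
import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import yaml

from .errors import FormatError, LayoutError

__all__ = [
    "Rect",
    "RegionLayout",
    "AcquisitionMeta",
    "PixelCalibration",
    "FrameStack",
    "load_frames",
    "extract_us_image",
    "calibrate_pixels",
    "load_layout",
    "load_meta",
]


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle [r0, r1) x [c0, c1)."""

    r0: int
    r1: int
    c0: int
    c1: int

    def __post_init__(self) -> None:
        if self.r1 <= self.r0 or self.c1 <= self.c0:
            raise LayoutError(f"empty rectangle {self}")

    @property
    def height(self) -> int:
        return self.r1 - self.r0

    @property
    def width(self) -> int:
        return self.c1 - self.c0

    @property
    def area(self) -> int:
        return self.height * self.width

    def contains(self, other: "Rect") -> bool:
        return (
            self.r0 <= other.r0
            and other.r1 <= self.r1
            and self.c0 <= other.c0
            and other.c1 <= self.c1
        )

    def within(self, shape: tuple[int, ...]) -> bool:
        return 0 <= self.r0 and self.r1 <= shape[0] and 0 <= self.c0 and self.c1 <= shape[1]

    def slices(self) -> tuple[slice, slice]:
        return slice(self.r0, self.r1), slice(self.c0, self.c1)

    def mask(self, shape: tuple[int, ...]) -> np.ndarray:
        m = np.zeros(shape[:2], dtype=bool)
        m[self.slices()] = True
        return m


@dataclass(frozen=True)
class RegionLayout:
    """Pixel geometry of the vendor display.

    ``colorbar_velocities`` are the velocity endpoints (cm/s) at the *top*
    and *bottom* of the colorbar strip; for a bidirectional map they have
    opposite signs.  ``scan_surface_row`` is the row of the probe face,
    from which depths are measured.
    """

    diagnostic_box: Rect
    color_box: Rect
    colorbar_strip: Rect | None = None
    colorbar_velocities: tuple[float, float] | None = None  # (top, bottom) cm/s
    scan_surface_row: int = 0

    def __post_init__(self) -> None:
        if not self.diagnostic_box.contains(self.color_box):
            raise LayoutError("color box must lie inside the diagnostic box")
        if self.colorbar_velocities is not None:
            top, bottom = self.colorbar_velocities
            if not (np.isfinite(top) and np.isfinite(bottom)):
                raise LayoutError("colorbar velocity endpoints must be finite")


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition settings attached to a frame stack.

    ``probe_model`` is ``"phased"`` or ``"convex"``; the fixed frame count
    retained from a 3 s video is 30 and 24 respectively.  Frame rates are
    only needed for the temporal-resolution parameter.
    """

    probe_model: str = "phased"
    configuration: str = "A"
    fov_cm: float = 12.0
    fr_duplex: float | None = None
    fr_bmode: float | None = None
    flow_rate: float | None = None  # mL/s
    layout: RegionLayout | None = None

    FIXED_FRAME_COUNTS = {"phased": 30, "convex": 24}

    def __post_init__(self) -> None:
        if self.fov_cm <= 0:
            raise ValueError("fov_cm must be positive")

    @property
    def n_fr_fixed(self) -> int:
        return self.FIXED_FRAME_COUNTS.get(self.probe_model, 30)


@dataclass(frozen=True)
class PixelCalibration:
    """Physical pixel spacing in mm/px (axial = along depth, lateral = across)."""

    mm_per_px_axial: float
    mm_per_px_lateral: float

    def __post_init__(self) -> None:
        if self.mm_per_px_axial <= 0 or self.mm_per_px_lateral <= 0:
            raise ValueError("pixel spacings must be positive")


@dataclass
class FrameStack:
    """Ordered 8-bit RGB frames with timing metadata."""

    frames: list[np.ndarray]
    frame_period: float
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self) -> None:
        if not self.frames:
            raise FormatError("a frame stack needs at least one frame")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be positive")
        shape = self.frames[0].shape
        for f in self.frames:
            if f.shape != shape:
                raise FormatError("all frames must share the same size")

    @property
    def n_fr(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.frames[0].shape


def _as_rgb(img: np.ndarray) -> np.ndarray:
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.ndim == 3 and img.shape[-1] == 4:
        img = img[..., :3]
    if img.ndim != 3 or img.shape[-1] != 3:
        raise FormatError(f"expected an RGB image, got shape {img.shape}")
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 255).astype(np.uint8)
    return img


def load_frames(
    path_spec: str | os.PathLike | Sequence[str],
    meta: AcquisitionMeta | None = None,
    fixed_count: int | None = None,
) -> FrameStack:
    """Load a frame sequence as a :class:`FrameStack`.

    ``path_spec`` may be a directory of numbered PNG/TIFF frames, a glob
    pattern, a multi-frame TIFF, or an explicit list of files.  Frames are
    ordered by filename and truncated to the configured fixed count
    (``meta.n_fr_fixed`` unless ``fixed_count`` overrides it) when more are
    present.
    """
    meta = meta or AcquisitionMeta()
    paths: list[str]
    if isinstance(path_spec, (str, os.PathLike)):
        p = Path(path_spec)
        if p.is_dir():
            imgs = [q for q in p.iterdir() if q.suffix.lower() in {".png", ".tif", ".tiff"}]
            # fixture directories may hold companion stills (e.g. bmode.png)
            # next to the numbered video frames: prefer the frame_* files
            numbered = [q for q in imgs if q.stem.lower().startswith("frame")]
            paths = sorted(str(q) for q in (numbered or imgs))
        elif any(ch in str(p) for ch in "*?["):
            paths = sorted(_glob.glob(str(p)))
        else:
            paths = [str(p)]
    else:
        paths = [str(q) for q in path_spec]
    if not paths:
        raise IOError(f"no frames found for {path_spec!r}")

    frames: list[np.ndarray] = []
    for path in paths:
        if not os.path.exists(path):
            raise IOError(f"frame file not found: {path}")
        try:
            img = iio.imread(path)
        except Exception as exc:  # noqa: BLE001 - normalize decoder errors
            raise IOError(f"unreadable frame {path}: {exc}") from exc
        if img.ndim == 4 or (img.ndim == 3 and img.shape[-1] not in (3, 4)):
            frames.extend(_as_rgb(page) for page in img)  # multi-frame TIFF
        else:
            frames.append(_as_rgb(img))

    limit = fixed_count if fixed_count is not None else meta.n_fr_fixed
    frames = frames[:limit]
    fr = meta.fr_duplex or 10.0
    return FrameStack(frames=frames, frame_period=1.0 / fr, meta=meta)


def extract_us_image(frame: np.ndarray, layout: RegionLayout) -> np.ndarray:
    """Zero every pixel outside the diagnostic box (and the colorbar strip).

    Removes the patient banner, settings readouts and the colorbar from the
    display so that only echographic content remains.  Idempotent; the
    input is not modified.
    """
    frame = np.asarray(frame)
    if not layout.diagnostic_box.within(frame.shape):
        raise LayoutError("diagnostic box exceeds the frame bounds")
    if layout.colorbar_strip is not None and not layout.colorbar_strip.within(frame.shape):
        raise LayoutError("colorbar strip exceeds the frame bounds")
    keep = layout.diagnostic_box.mask(frame.shape)
    if layout.colorbar_strip is not None:
        keep &= ~layout.colorbar_strip.mask(frame.shape)
    out = frame.copy()
    out[~keep] = 0
    return out


def calibrate_pixels(
    layout: RegionLayout,
    fov_cm: float,
    mm_per_px_lateral: float | None = None,
) -> PixelCalibration:
    """Derive the mm-per-pixel spacing from the displayed depth of field.

    The diagnostic box spans ``fov_cm`` of depth, so the axial spacing is
    ``10 * fov_cm / box_height``.  Pixels are assumed isotropic unless a
    lateral spacing override is given.
    """
    h = layout.diagnostic_box.height
    if h <= 0:
        raise LayoutError("diagnostic box height must be positive")
    axial = 10.0 * fov_cm / h
    lateral = mm_per_px_lateral if mm_per_px_lateral is not None else axial
    return PixelCalibration(mm_per_px_axial=axial, mm_per_px_lateral=lateral)


# ---------------------------------------------------------------------------
# config (YAML/JSON) plumbing


def _rect_from(obj) -> Rect:
    if isinstance(obj, dict):
        return Rect(int(obj["r0"]), int(obj["r1"]), int(obj["c0"]), int(obj["c1"]))
    r0, r1, c0, c1 = obj
    return Rect(int(r0), int(r1), int(c0), int(c1))


def layout_from_dict(d: dict) -> RegionLayout:
    strip = d.get("colorbar_strip")
    vel = d.get("colorbar_velocities")
    return RegionLayout(
        diagnostic_box=_rect_from(d["diagnostic_box"]),
        color_box=_rect_from(d["color_box"]),
        colorbar_strip=_rect_from(strip) if strip is not None else None,
        colorbar_velocities=tuple(float(v) for v in vel) if vel is not None else None,
        scan_surface_row=int(d.get("scan_surface_row", 0)),
    )


def layout_to_dict(layout: RegionLayout) -> dict:
    def rect_d(r: Rect) -> dict:
        return {"r0": r.r0, "r1": r.r1, "c0": r.c0, "c1": r.c1}

    d: dict = {
        "diagnostic_box": rect_d(layout.diagnostic_box),
        "color_box": rect_d(layout.color_box),
        "scan_surface_row": layout.scan_surface_row,
    }
    if layout.colorbar_strip is not None:
        d["colorbar_strip"] = rect_d(layout.colorbar_strip)
    if layout.colorbar_velocities is not None:
        d["colorbar_velocities"] = list(layout.colorbar_velocities)
    return d


def _read_config(path: str | os.PathLike) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def load_layout(path: str | os.PathLike) -> RegionLayout:
    """Read a :class:`RegionLayout` from a YAML or JSON file."""
    d = _read_config(path)
    return layout_from_dict(d.get("layout", d))


def load_meta(path: str | os.PathLike) -> AcquisitionMeta:
    """Read an :class:`AcquisitionMeta` (with nested layout) from YAML/JSON."""
    d = _read_config(path)
    layout = layout_from_dict(d["layout"]) if "layout" in d else None
    fields = {
        k: d[k]
        for k in ("probe_model", "configuration", "fov_cm", "fr_duplex", "fr_bmode", "flow_rate")
        if k in d
    }
    return AcquisitionMeta(layout=layout, **fields)


def with_layout(meta: AcquisitionMeta, layout: RegionLayout) -> AcquisitionMeta:
    return replace(meta, layout=layout)
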
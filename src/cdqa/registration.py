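"""Registration error: color bleeding outside the vessel walls.

With color-write priority at maximum, any misregistration of the Doppler
data shows up as colored pixels beyond the vessel boundaries.  A companion
B-mode image (probe held still) provides the geometry: the anechoic lumen
is segmented with an adaptive brightness threshold and its upper and lower
walls are fitted with straight lines.  On each average image of the duplex
video the percentage registration error is

    RE%_i = n_out_i / n_box_i * 100

where n_box_i counts color-box pixels with intensity above th_blind and
n_out_i counts those lying above the upper wall line or below the lower
one.  The overall RE% is the mean over the N average images, its SD the
sample SD.  Ideal systems score 0%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import LumenNotFoundError, NoFlowError
from .io import RegionLayout
from .preprocess import DEFAULT_TH_BLIND, AverageImage, intensity_map

__all__ = [
    "VesselBoundaries",
    "RegistrationResult",
    "RegistrationSettings",
    "detect_vessel_boundaries",
    "estimate_registration_error",
]


@dataclass(frozen=True)
class RegistrationSettings:
    th_sat: float = 0.35
    N: int = 6
    M: int | None = None
    th_blind: float = DEFAULT_TH_BLIND
    c_b: float = 0.5  # th_b = c_b * mean brightness V of the diagnostic box


@dataclass
class VesselBoundaries:
    """Straight-line fits (row = slope*col + intercept) of the two walls."""

    upper_line: tuple[float, float]  # (slope, intercept); smaller rows = shallower
    lower_line: tuple[float, float]
    th_b: float
    lumen_mask: np.ndarray
    touches_box: bool = False  # lumen reached the diagnostic-box border


@dataclass
class RegistrationResult:
    RE_pct: float
    sigma_RE: float
    per_image: list[float] = field(default_factory=list)
    counts: list[tuple[int, int]] = field(default_factory=list)  # (n_out, n_box)


def detect_vessel_boundaries(
    bmode: np.ndarray,
    layout: RegionLayout,
    c_b: float = 0.5,
) -> VesselBoundaries:
    """Segment the dark lumen of a masked B-mode image and fit its walls.

    Brightness is the HSV Value (max channel, scaled to [0, 1]); the
    adaptive threshold th_b = c_b * mean(V over the diagnostic box) splits
    anechoic lumen from tissue speckle.  The lumen is the largest connected
    dark component; per-column extreme rows are fitted by least squares.
    """
    img = np.asarray(bmode, dtype=float)
    v = img.max(axis=-1) / 255.0 if img.ndim == 3 else img / 255.0
    box = layout.diagnostic_box
    box_mask = box.mask(v.shape)
    th_b = c_b * float(v[box_mask].mean())
    dark = (v < th_b) & box_mask
    labels, nlab = ndimage.label(dark)
    if nlab == 0:
        raise LumenNotFoundError("no dark component below the adaptive threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, nlab + 1))
    lumen = labels == (1 + int(np.argmax(sizes)))

    rows, cols = np.nonzero(lumen)
    touches = rows.min() <= box.r0 or rows.max() >= box.r1 - 1
    tops, bottoms, cs = [], [], []
    for c in np.unique(cols):
        rr = rows[cols == c]
        cs.append(c)
        tops.append(rr.min())
        bottoms.append(rr.max())
    cs = np.asarray(cs, dtype=float)
    if cs.size >= 2:
        upper = tuple(np.polyfit(cs, np.asarray(tops, dtype=float), 1))
        lower = tuple(np.polyfit(cs, np.asarray(bottoms, dtype=float), 1))
    else:
        upper = (0.0, float(tops[0]))
        lower = (0.0, float(bottoms[0]))
    return VesselBoundaries(
        upper_line=(float(upper[0]), float(upper[1])),
        lower_line=(float(lower[0]), float(lower[1])),
        th_b=th_b,
        lumen_mask=lumen,
        touches_box=bool(touches),
    )


def estimate_registration_error(
    avgs: list[AverageImage],
    bounds: VesselBoundaries,
    layout: RegionLayout,
    th_blind: float = DEFAULT_TH_BLIND,
) -> RegistrationResult:
    """Count above-threshold color pixels outside the wall lines.

    The two wall lines split the color box into an inside band and two
    outer sub-boxes; pixels exactly on a line count as inside (conservative
    toward RE = 0).
    """
    per_image: list[float] = []
    counts: list[tuple[int, int]] = []
    cb = layout.color_box
    for avg in avgs:
        imap = intensity_map(avg, th_blind)
        sub = imap.I[cb.slices()]
        rows, cols = np.nonzero(sub > th_blind)
        n_box = rows.size
        if n_box == 0:
            raise NoFlowError(f"average image {avg.index}: no color pixels above th_blind")
        r_abs = rows + cb.r0
        c_abs = cols + cb.c0
        up = bounds.upper_line[0] * c_abs + bounds.upper_line[1]
        lo = bounds.lower_line[0] * c_abs + bounds.lower_line[1]
        n_out = int(np.count_nonzero((r_abs < up) | (r_abs > lo)))
        per_image.append(100.0 * n_out / n_box)
        counts.append((n_out, n_box))

    arr = np.asarray(per_image)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return RegistrationResult(
        RE_pct=float(arr.mean()), sigma_RE=sd, per_image=per_image, counts=counts
    )
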
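"""Temporal resolution of duplex imaging.

Running Color Doppler on top of B-mode costs frame rate, and the cost grows
with the fraction of the display devoted to color.  The index

    TR = (FR_duplex / FR_Bmode) * (A_color / A_tot)

combines the frame-rate ratio with the areal fraction of the color box in
the diagnostic box.  Under the assumption that Doppler processing can at
best halve the B-mode frame rate, TR peaks at 0.5 when the color box
covers the whole diagnostic area.  A_color excludes the pixels of the
color-box perimeter (drawn as a graphic overlay, not Doppler data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, LayoutError
from .io import RegionLayout

__all__ = ["TemporalResolutionResult", "measure_areas", "estimate_tr"]


@dataclass
class TemporalResolutionResult:
    TR: float
    sigma_TR: float
    A_color: int
    A_tot: int
    fr_duplex: float
    fr_bmode: float


def measure_areas(layout: RegionLayout) -> tuple[int, int]:
    """Pixel areas (A_tot, A_color) of the diagnostic box and color-box interior.

    The color-box perimeter ring is excluded from A_color.
    """
    if not layout.diagnostic_box.contains(layout.color_box):
        raise LayoutError("color box must lie inside the diagnostic box")
    a_tot = layout.diagnostic_box.area
    cb = layout.color_box
    a_color = max(cb.height - 2, 0) * max(cb.width - 2, 0)
    return a_tot, a_color


def estimate_tr(
    fr_duplex: float,
    fr_bmode: float,
    a_color: float,
    a_tot: float,
    sigma_TR: float = 0.0,
) -> TemporalResolutionResult:
    """Evaluate TR = (FR_duplex/FR_Bmode) * (A_color/A_tot).

    ``sigma_TR`` is supplied externally (from the Monte-Carlo uncertainty
    module or repeated acquisitions); the formula itself is deterministic.
    """
    if fr_bmode <= 0 or fr_duplex <= 0 or a_tot <= 0 or a_color < 0:
        raise DegenerateInputError("frame rates and areas must be positive")
    tr = (fr_duplex / fr_bmode) * (a_color / a_tot)
    return TemporalResolutionResult(
        TR=float(tr),
        sigma_TR=float(sigma_TR),
        A_color=int(a_color),
        A_tot=int(a_tot),
        fr_duplex=fr_duplex,
        fr_bmode=fr_bmode,
    )
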
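"""Score normalization and the Kiviat (radar) performance index.

The five QA parameters live on different scales and have different optima
(BA: 0 deg, RE: 0 %, AMVS: 1, VeMeA: 0, TR: 0.5).  They are mapped onto a
common [0, 1] scale where 1 is ideal:

    BA*    = 1 - BA / BA_lim          (BA_lim = 45 deg, the largest
                                       blind angle considered plausible)
    RE*    = 1 - RE / 100
    AMVS*  = 1 - |AMVS - 1|
    VeMeA* = 1 - VeMeA
    TR*    = sqrt(TR / TR_opt)        (TR_opt = 0.5; the square root
                                       stretches the small TR dynamics)

The five scores are drawn as radii on a five-axis Kiviat diagram in the
fixed order (BA*, RE*, AMVS*, VeMeA*, TR*), axes 72 degrees apart.  The
polygon area, normalized to the regular "gold standard" pentagon with all
radii 1, is the composite performance index

    S* = (1/5) * sum_i r_i * r_{i+1}        (cyclic)

with first-order SD propagation

    sigma_S*^2 = sum_i ((r_{i-1} + r_{i+1}) / 5)^2 * sigma_i^2.

S* = 1 for an ideal system; larger areas mean better overall Color Doppler
performance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = [
    "BA_LIM",
    "TR_OPT",
    "AXIS_ORDER",
    "NormalizedScores",
    "KiviatResult",
    "normalize_parameters",
    "kiviat_area",
    "render_kiviat",
]

BA_LIM = 45.0  # degrees
TR_OPT = 0.5
AXIS_ORDER = ("BA", "RE", "AMVS", "VeMeA", "TR")


@dataclass(frozen=True)
class NormalizedScores:
    """Unit-range scores (value, SD) in the fixed axis order."""

    BA: tuple[float, float]
    RE: tuple[float, float]
    AMVS: tuple[float, float]
    VeMeA: tuple[float, float]
    TR: tuple[float, float]
    clipped: tuple[str, ...] = ()  # parameters whose score was clipped to [0, 1]

    def radii(self) -> np.ndarray:
        return np.array([getattr(self, k)[0] for k in AXIS_ORDER])

    def sds(self) -> np.ndarray:
        return np.array([getattr(self, k)[1] for k in AXIS_ORDER])


@dataclass(frozen=True)
class KiviatResult:
    S_star: float
    sigma_S_star: float
    radii: tuple[float, ...]
    sds: tuple[float, ...]
    axis_order: tuple[str, ...] = AXIS_ORDER


def _clip01(name: str, value: float, clipped: list[str]) -> float:
    if value < 0.0 or value > 1.0:
        clipped.append(name)
        return min(max(value, 0.0), 1.0)
    return value


def normalize_parameters(
    BA: tuple[float, float],
    RE: tuple[float, float],
    AMVS: tuple[float, float],
    VeMeA: tuple[float, float],
    TR: tuple[float, float],
    ba_lim: float = BA_LIM,
    tr_opt: float = TR_OPT,
) -> NormalizedScores:
    """Map the five raw parameters (value, SD) onto the unit scale.

    SDs propagate to first order; scores are clipped to [0, 1] and the
    clipped parameter names are recorded.
    """
    ba, s_ba = BA
    re, s_re = RE
    amvs, s_amvs = AMVS
    vemea, s_vemea = VeMeA
    tr, s_tr = TR
    if tr < 0:
        raise ParameterError("TR must be non-negative")
    clipped: list[str] = []

    ba_star = _clip01("BA", 1.0 - ba / ba_lim, clipped)
    re_star = _clip01("RE", 1.0 - re / 100.0, clipped)
    amvs_star = _clip01("AMVS", 1.0 - abs(amvs - 1.0), clipped)
    vemea_star = _clip01("VeMeA", 1.0 - vemea, clipped)
    tr_star = _clip01("TR", math.sqrt(tr / tr_opt), clipped)
    s_tr_star = s_tr / (2.0 * math.sqrt(tr * tr_opt)) if tr > 0 else 0.0

    return NormalizedScores(
        BA=(ba_star, s_ba / ba_lim),
        RE=(re_star, s_re / 100.0),
        AMVS=(amvs_star, s_amvs),
        VeMeA=(vemea_star, s_vemea),
        TR=(tr_star, s_tr_star),
        clipped=tuple(clipped),
    )


def kiviat_area(scores: NormalizedScores) -> KiviatResult:
    """Normalized pentagon area S* and its propagated SD.

    With vertices at radius r_i on axes 72 degrees apart, the shoelace area
    is (sin 72 / 2) * sum_i r_i r_{i+1}; the gold-standard pentagon (all
    r_i = 1) has area 5 * (sin 72 / 2), so the ratio reduces to the cyclic
    product form S* = sum_i r_i r_{i+1} / 5.
    """
    r = scores.radii()
    s = scores.sds()
    if np.any(r < 0) or np.any(r > 1):
        raise ParameterError("scores must be within [0, 1]")
    r_next = np.roll(r, -1)
    r_prev = np.roll(r, 1)
    s_star = float(np.sum(r * r_next) / 5.0)
    sigma = float(np.sqrt(np.sum(((r_prev + r_next) / 5.0) ** 2 * s**2)))
    return KiviatResult(
        S_star=s_star,
        sigma_S_star=sigma,
        radii=tuple(float(x) for x in r),
        sds=tuple(float(x) for x in s),
    )


def render_kiviat(result: KiviatResult, path: str, title: str | None = None) -> None:
    """Write a five-axis radar plot (SVG or PNG) with the gold-standard overlay.

    SVG output is deterministic: identical inputs produce identical bytes.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    with matplotlib.rc_context({"svg.hashsalt": "cdqa"}):
        angles = np.deg2rad(90.0 - 72.0 * np.arange(6))  # close the polygon
        radii = np.append(result.radii, result.radii[0])
        gold = np.ones(6)

        fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
        ax.plot(angles, gold, color="0.4", lw=1.0, ls="--", label="gold standard")
        ax.plot(angles, radii, color="tab:red", lw=1.5)
        ax.fill(angles, radii, color="tab:red", alpha=0.25)
        ax.set_xticks(angles[:-1])
        labels = [f"{k}*" for k in result.axis_order]
        ax.set_xticklabels(labels)
        ax.set_ylim(0, 1.05)
        ax.set_yticks([0.2, 0.4, 0.6, 0.8, 1.0])
        txt = title or f"S* = {result.S_star:.2f} ± {result.sigma_S_star:.2f}"
        ax.set_title(txt)
        fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
        plt.close(fig)
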
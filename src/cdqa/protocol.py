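"""End-to-end QA protocol for one probe-configuration pair.

Runs the five estimators on their acquisitions, attaches the Monte-Carlo
method uncertainty to each repeatability SD, normalizes the parameters,
computes the Kiviat composite index, and emits a consolidated report
(JSON + CSV + optional SVG radar plot).

Two input modes exist:

* **acquisition mode** - frame stacks (real or synthetic) are processed by
  the estimators;
* **precomputed mode** - the five (mean, SD) pairs are supplied directly
  (e.g. from a published table or an external analysis) and only the
  scoring stage runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import __version__
from .blind_angle import BlindAngleSettings, estimate_blind_angle
from .errors import CdqaError
from .io import FrameStack, calibrate_pixels, extract_us_image
from .mcs import TABLE_SPECS, McsConfig, combine_sd, run_mcs, tr_specs
from .preprocess import make_average_images
from .registration import RegistrationSettings, detect_vessel_boundaries, estimate_registration_error
from .scoring import KiviatResult, NormalizedScores, kiviat_area, normalize_parameters, render_kiviat
from .temporal import estimate_tr, measure_areas
from .velocity import (
    VelocitySettings,
    calibrate_colorbar,
    estimate_amvs,
    estimate_velocity,
    estimate_vemea,
    theoretical_flow_velocity,
)

__all__ = [
    "ProtocolConfig",
    "ProtocolReport",
    "run_protocol",
    "score_from_estimates",
    "tabulate_reports",
    "mcs_sd_blind_angle",
    "mcs_sd_registration",
    "mcs_sd_velocity",
    "mcs_sd_temporal",
]

PARAMETER_NAMES = ("BA", "RE", "AMVS", "VeMeA", "TR")


@dataclass
class ProtocolConfig:
    """Inputs for one protocol run.

    Acquisition mode fills the ``*_stack`` / image fields (synthetic
    bundles or loaded recordings); precomputed mode fills ``precomputed``
    with five (mean, sd) pairs keyed by parameter name.
    """

    label: str = "system"
    precomputed: dict[str, tuple[float, float]] | None = None

    ba_stack: FrameStack | None = None
    re_stack: FrameStack | None = None
    re_bmode: np.ndarray | None = None
    amvs_stacks: tuple[FrameStack, FrameStack] | None = None  # (Q1, Q2)
    vemea_stack: FrameStack | None = None
    vessel_diameter_mm: float = 5.0
    profile_factor: float = 2.0

    ba_settings: BlindAngleSettings = field(default_factory=BlindAngleSettings)
    re_settings: RegistrationSettings = field(default_factory=RegistrationSettings)
    vel_settings: VelocitySettings = field(default_factory=VelocitySettings)

    mcs_iterations: int = 0  # 0 disables the Monte-Carlo uncertainty stage
    mcs_seed: int = 0


@dataclass
class ProtocolReport:
    label: str
    parameters: dict[str, dict]  # name -> {mean, sd_rep, sd_mcs, sd}
    scores: NormalizedScores | None
    kiviat: KiviatResult | None
    missing: tuple[str, ...] = ()
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "parameters": self.parameters,
            "missing": list(self.missing),
            "provenance": self.provenance,
        }
        if self.scores is not None:
            d["scores"] = {
                k: {"value": getattr(self.scores, k)[0], "sd": getattr(self.scores, k)[1]}
                for k in PARAMETER_NAMES
            }
            d["clipped"] = list(self.scores.clipped)
        if self.kiviat is not None:
            d["S_star"] = self.kiviat.S_star
            d["sigma_S_star"] = self.kiviat.sigma_S_star
        return d

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Monte-Carlo adapters: one evaluator closure per parameter pipeline


def _prep(stack: FrameStack) -> tuple[list[np.ndarray], "object", "object"]:
    layout = stack.meta.layout
    if layout is None:
        raise CdqaError("frame stack carries no region layout")
    calib = calibrate_pixels(layout, stack.meta.fov_cm)
    masked = [extract_us_image(f, layout) for f in stack.frames]
    return masked, layout, calib


def mcs_sd_blind_angle(
    stack: FrameStack, settings: BlindAngleSettings, iterations: int, seed: int
) -> float:
    """Method-uncertainty SD of the blind angle under input randomization."""
    masked, layout, calib = _prep(stack)
    N = settings.N
    M = settings.M or stack.n_fr // N
    base = FrameStack(frames=masked, frame_period=stack.frame_period, meta=stack.meta)

    def evaluator(params: dict, groups) -> float:
        s = dataclasses.replace(
            settings,
            th_sat=params["th_sat"],
            k=max(int(params["k"]), 1),
            d_mm=max(params["d_mm"], 0.05),
            th_blind=params["th_blind"],
        )
        avgs = make_average_images(base, N, M, th_sat=s.th_sat, groups=groups, color_only=True)
        return estimate_blind_angle(avgs, layout, calib, s).BA

    cfg = McsConfig(iterations=iterations, seed=seed, specs=TABLE_SPECS["ba"],
                    n_fr=stack.n_fr, N=N, M=M)
    return run_mcs(evaluator, cfg).sd_mcs


def mcs_sd_registration(
    stack: FrameStack,
    bmode: np.ndarray,
    settings: RegistrationSettings,
    iterations: int,
    seed: int,
) -> float:
    masked, layout, calib = _prep(stack)
    N = settings.N
    M = settings.M or stack.n_fr // N
    base = FrameStack(frames=masked, frame_period=stack.frame_period, meta=stack.meta)
    bmode_masked = extract_us_image(bmode, layout)

    def evaluator(params: dict, groups) -> float:
        bounds = detect_vessel_boundaries(
            bmode_masked, layout, c_b=settings.c_b * params["c_b_scale"]
        )
        avgs = make_average_images(base, N, M, th_sat=params["th_sat"], groups=groups, color_only=True)
        return estimate_registration_error(avgs, bounds, layout, params["th_blind"]).RE_pct

    cfg = McsConfig(iterations=iterations, seed=seed, specs=TABLE_SPECS["re"],
                    n_fr=stack.n_fr, N=N, M=M)
    return run_mcs(evaluator, cfg).sd_mcs


def mcs_sd_velocity(
    stack: FrameStack,
    settings: VelocitySettings,
    mode: str,
    iterations: int,
    seed: int,
) -> float:
    masked, layout, calib = _prep(stack)
    N = settings.N
    M = settings.M or stack.n_fr // N
    base = FrameStack(frames=masked, frame_period=stack.frame_period, meta=stack.meta)
    cal = calibrate_colorbar(stack.frames[0], layout)
    key = "amvs" if mode == "peak" else "vemea"

    def evaluator(params: dict, groups) -> float:
        s = dataclasses.replace(
            settings,
            th_sat=params["th_sat"],
            D_mm=max(params["D_mm"], 1.0),
            center_offset_mm=params["x0_mm"],
        )
        avgs = make_average_images(base, N, M, th_sat=s.th_sat, groups=groups, color_only=True)
        return estimate_velocity(avgs, cal, calib, mode=mode, settings=s).value

    cfg = McsConfig(iterations=iterations, seed=seed, specs=TABLE_SPECS[key],
                    n_fr=stack.n_fr, N=N, M=M)
    return run_mcs(evaluator, cfg).sd_mcs


def mcs_sd_temporal(
    fr_duplex: float, fr_bmode: float, a_color: float, a_tot: float,
    iterations: int, seed: int,
) -> float:
    def evaluator(params: dict, groups) -> float:
        return estimate_tr(
            params["fr_duplex"], params["fr_bmode"], params["a_color"], params["a_tot"]
        ).TR

    cfg = McsConfig(
        iterations=iterations,
        seed=seed,
        specs=tr_specs(fr_duplex, fr_bmode, a_color, a_tot),
        resample=False,
    )
    return run_mcs(evaluator, cfg).sd_mcs


# ---------------------------------------------------------------------------
# protocol


def score_from_estimates(
    estimates: dict[str, tuple[float, float]], label: str = "system"
) -> ProtocolReport:
    """Scoring stage only: five (mean, SD) pairs -> normalized scores + S*."""
    missing = tuple(k for k in PARAMETER_NAMES if k not in estimates)
    params = {
        k: {"mean": v[0], "sd_rep": v[1], "sd_mcs": 0.0, "sd": v[1]}
        for k, v in estimates.items()
    }
    if missing:
        return ProtocolReport(label=label, parameters=params, scores=None,
                              kiviat=None, missing=missing)
    scores = normalize_parameters(*[estimates[k] for k in PARAMETER_NAMES])
    return ProtocolReport(
        label=label,
        parameters=params,
        scores=scores,
        kiviat=kiviat_area(scores),
        provenance=_provenance(estimates),
    )


def _provenance(obj) -> dict:
    digest = hashlib.sha256(repr(sorted(repr(obj).encode()))[:4096].encode()).hexdigest()[:16]
    return {"version": __version__, "config_sha256_16": digest}


def run_protocol(cfg: ProtocolConfig) -> ProtocolReport:
    """Execute the full five-parameter protocol and score it.

    Estimator failures do not abort the run: the affected parameter is
    flagged as missing and no composite index is produced.
    """
    if cfg.precomputed is not None:
        return score_from_estimates(cfg.precomputed, label=cfg.label)

    estimates: dict[str, tuple[float, float]] = {}
    params: dict[str, dict] = {}
    missing: list[str] = []

    def record(name: str, mean: float, sd_rep: float, sd_mcs: float) -> None:
        sd = combine_sd(sd_rep, sd_mcs)
        params[name] = {"mean": mean, "sd_rep": sd_rep, "sd_mcs": sd_mcs, "sd": sd}
        estimates[name] = (mean, sd)

    # blind angle
    try:
        if cfg.ba_stack is None:
            raise CdqaError("no blind-angle acquisition")
        masked, layout, calib = _prep(cfg.ba_stack)
        s = cfg.ba_settings
        M = s.M or cfg.ba_stack.n_fr // s.N
        base = FrameStack(frames=masked, frame_period=cfg.ba_stack.frame_period,
                          meta=cfg.ba_stack.meta)
        avgs = make_average_images(base, s.N, M, th_sat=s.th_sat, color_only=True)
        res = estimate_blind_angle(avgs, layout, calib, s)
        sd_mcs = (
            mcs_sd_blind_angle(cfg.ba_stack, s, cfg.mcs_iterations, cfg.mcs_seed)
            if cfg.mcs_iterations
            else 0.0
        )
        record("BA", res.BA, res.sigma_BA, sd_mcs)
    except CdqaError:
        missing.append("BA")

    # registration error
    try:
        if cfg.re_stack is None or cfg.re_bmode is None:
            raise CdqaError("no registration-error acquisition")
        masked, layout, calib = _prep(cfg.re_stack)
        s = cfg.re_settings
        M = s.M or cfg.re_stack.n_fr // s.N
        base = FrameStack(frames=masked, frame_period=cfg.re_stack.frame_period,
                          meta=cfg.re_stack.meta)
        bounds = detect_vessel_boundaries(
            extract_us_image(cfg.re_bmode, layout), layout, c_b=s.c_b
        )
        avgs = make_average_images(base, s.N, M, th_sat=s.th_sat, color_only=True)
        res = estimate_registration_error(avgs, bounds, layout, s.th_blind)
        sd_mcs = (
            mcs_sd_registration(cfg.re_stack, cfg.re_bmode, s,
                                cfg.mcs_iterations, cfg.mcs_seed)
            if cfg.mcs_iterations
            else 0.0
        )
        record("RE", res.RE_pct, res.sigma_RE, sd_mcs)
    except CdqaError:
        missing.append("RE")

    # velocity parameters
    def run_velocity(stack: FrameStack, mode: str):
        masked, layout, calib = _prep(stack)
        s = cfg.vel_settings
        M = s.M or stack.n_fr // s.N
        base = FrameStack(frames=masked, frame_period=stack.frame_period, meta=stack.meta)
        cal = calibrate_colorbar(stack.frames[0], layout)
        avgs = make_average_images(base, s.N, M, th_sat=s.th_sat, color_only=True)
        return estimate_velocity(avgs, cal, calib, mode=mode, settings=s)

    try:
        if cfg.amvs_stacks is None:
            raise CdqaError("no velocity-sensitivity acquisitions")
        st1, st2 = cfg.amvs_stacks
        v1 = run_velocity(st1, "peak")
        v2 = run_velocity(st2, "peak")
        vth1 = theoretical_flow_velocity(st1.meta.flow_rate, cfg.vessel_diameter_mm,
                                         "peak", cfg.profile_factor)
        vth2 = theoretical_flow_velocity(st2.meta.flow_rate, cfg.vessel_diameter_mm,
                                         "peak", cfg.profile_factor)
        res = estimate_amvs(v1, v2, vth1, vth2)
        sd_mcs = 0.0
        if cfg.mcs_iterations:
            s1 = mcs_sd_velocity(st1, cfg.vel_settings, "peak", cfg.mcs_iterations, cfg.mcs_seed)
            s2 = mcs_sd_velocity(st2, cfg.vel_settings, "peak", cfg.mcs_iterations, cfg.mcs_seed + 1)
            dv_th = vth2[0] - vth1[0]
            sd_mcs = float(np.hypot(s1, s2) / abs(dv_th))
        record("AMVS", res.AMVS, res.sigma_AMVS, sd_mcs)
    except CdqaError:
        missing.append("AMVS")

    try:
        if cfg.vemea_stack is None:
            raise CdqaError("no velocity-accuracy acquisition")
        vbar = run_velocity(cfg.vemea_stack, "mean")
        vth = theoretical_flow_velocity(cfg.vemea_stack.meta.flow_rate,
                                        cfg.vessel_diameter_mm, "mean")
        res = estimate_vemea(vbar, vth)
        sd_mcs = 0.0
        if cfg.mcs_iterations:
            s_v = mcs_sd_velocity(cfg.vemea_stack, cfg.vel_settings, "mean",
                                  cfg.mcs_iterations, cfg.mcs_seed + 2)
            sd_mcs = s_v / vth[0]
        record("VeMeA", res.VeMeA, res.sigma_VeMeA, sd_mcs)
    except CdqaError:
        missing.append("VeMeA")

    # temporal resolution (layout + frame rates from any available stack)
    try:
        stack = cfg.ba_stack or cfg.re_stack or cfg.vemea_stack
        if stack is None or stack.meta.fr_duplex is None or stack.meta.fr_bmode is None:
            raise CdqaError("no frame rates for temporal resolution")
        layout = stack.meta.layout
        a_tot, a_color = measure_areas(layout)
        res = estimate_tr(stack.meta.fr_duplex, stack.meta.fr_bmode, a_color, a_tot)
        sd_mcs = (
            mcs_sd_temporal(stack.meta.fr_duplex, stack.meta.fr_bmode, a_color, a_tot,
                            cfg.mcs_iterations, cfg.mcs_seed + 3)
            if cfg.mcs_iterations
            else 0.0
        )
        record("TR", res.TR, 0.0, sd_mcs)
    except CdqaError:
        missing.append("TR")

    scores = kiv = None
    if not missing:
        scores = normalize_parameters(*[estimates[k] for k in PARAMETER_NAMES])
        kiv = kiviat_area(scores)
    return ProtocolReport(
        label=cfg.label,
        parameters=params,
        scores=scores,
        kiviat=kiv,
        missing=tuple(missing),
        provenance=_provenance(params),
    )


def tabulate_reports(reports: list[ProtocolReport]) -> pd.DataFrame:
    """One row per report: the five normalized scores and S* +- sigma."""
    if not reports:
        raise ValueError("need at least one report")
    recs = []
    for rep in reports:
        rec = {"label": rep.label}
        for k in PARAMETER_NAMES:
            if rep.scores is not None:
                rec[f"{k}_star"] = getattr(rep.scores, k)[0]
                rec[f"{k}_star_sd"] = getattr(rep.scores, k)[1]
            else:
                rec[f"{k}_star"] = np.nan
                rec[f"{k}_star_sd"] = np.nan
        rec["S_star"] = rep.kiviat.S_star if rep.kiviat else np.nan
        rec["S_star_sd"] = rep.kiviat.sigma_S_star if rep.kiviat else np.nan
        recs.append(rec)
    cols = ["label"]
    for k in PARAMETER_NAMES:
        cols += [f"{k}_star", f"{k}_star_sd"]
    cols += ["S_star", "S_star_sd"]
    return pd.DataFrame.from_records(recs, columns=cols)
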
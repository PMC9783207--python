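"""Monte-Carlo estimation of the image-analysis measurement uncertainty.

The five estimators depend on method settings (saturation threshold,
median kernel, blind threshold, axis spacing, segment placement, measured
areas, frame rates) whose exact values are themselves uncertain.  Their
contribution to the measurement uncertainty is quantified by a Monte-Carlo
simulation: each setting is redrawn from a uniform distribution declared
as mean +- SD (so the support half-width is SD * sqrt(3)), the frames
entering the N average images are re-randomized without repetition, the
estimator is re-evaluated, and the SD over iterations is taken as the
method uncertainty.  It combines with the repeatability SD by
root-sum-square.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import McsError, ParameterError, PartitionError

__all__ = [
    "UniformSpec",
    "McsConfig",
    "McsResult",
    "sample_inputs",
    "resample_frames",
    "run_mcs",
    "combine_sd",
    "TABLE_SPECS",
]


@dataclass(frozen=True)
class UniformSpec:
    """Uniform distribution declared as mean +- SD.

    ``uniform_param="sd"`` reads the +- figure as a standard deviation
    (half-width = sd * sqrt(3)); ``"halfwidth"`` reads it as the support
    half-width directly.  ``integer`` rounds each draw to the nearest
    integer (half away from zero).
    """

    name: str
    mean: float
    sd: float
    integer: bool = False
    uniform_param: str = "sd"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ParameterError("sd must be >= 0")
        if self.uniform_param not in ("sd", "halfwidth"):
            raise ParameterError("uniform_param must be 'sd' or 'halfwidth'")

    @property
    def half_width(self) -> float:
        return self.sd * math.sqrt(3.0) if self.uniform_param == "sd" else self.sd


@dataclass
class McsConfig:
    iterations: int = 10_000
    seed: int | None = None
    specs: list[UniformSpec] = field(default_factory=list)
    resample: bool = True  # re-randomize the frame-to-average-image assignment
    n_fr: int = 30
    N: int = 6
    M: int = 5

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ParameterError("iterations must be >= 1")


@dataclass
class McsResult:
    sd_mcs: float
    values: np.ndarray
    n_failed: int = 0


#: Per-parameter uniform input distributions used by the QA protocol.
TABLE_SPECS: dict[str, list[UniformSpec]] = {
    "ba": [
        UniformSpec("th_sat", 0.35, 0.01),
        UniformSpec("k", 4, 1, integer=True),
        UniformSpec("d_mm", 1.0, 0.3),
        UniformSpec("th_blind", 10, 1, integer=True),
    ],
    "re": [
        UniformSpec("c_b_scale", 1.0, 0.06),  # th_b = mu_b +- 6% of mu_b
        UniformSpec("th_sat", 0.35, 0.01),
        UniformSpec("th_blind", 10, 1, integer=True),
    ],
    "amvs": [
        UniformSpec("th_sat", 0.35, 0.01),
        UniformSpec("D_mm", 20.0, 1.0),
        UniformSpec("x0_mm", 0.0, 1.0),  # first-segment position offset on the axis
    ],
    "vemea": [
        UniformSpec("th_sat", 0.35, 0.01),
        UniformSpec("D_mm", 20.0, 1.0),
        UniformSpec("x0_mm", 0.0, 1.0),
    ],
}


def tr_specs(fr_duplex: float, fr_bmode: float, a_color: float, a_tot: float) -> list[UniformSpec]:
    """Uniform specs for the temporal-resolution inputs (+-1 frame/s, +-3% areas)."""
    return [
        UniformSpec("fr_duplex", fr_duplex, 1.0),
        UniformSpec("fr_bmode", fr_bmode, 1.0),
        UniformSpec("a_color", a_color, 0.03 * a_color),
        UniformSpec("a_tot", a_tot, 0.03 * a_tot),
    ]


def sample_inputs(specs: Sequence[UniformSpec], rng: np.random.Generator) -> dict[str, float]:
    """Draw one value per spec from its uniform support."""
    out: dict[str, float] = {}
    for sp in specs:
        v = rng.uniform(sp.mean - sp.half_width, sp.mean + sp.half_width)
        if sp.integer:
            v = math.floor(v + 0.5) if v >= 0 else math.ceil(v - 0.5)
        out[sp.name] = float(v)
    return out


def resample_frames(
    n_fr: int, N: int, M: int, rng: np.random.Generator
) -> list[list[int]]:
    """Randomize which frames enter each average image, without repetition."""
    if N * M > n_fr:
        raise PartitionError(f"cannot place {N}x{M} frames into {n_fr}")
    idx = rng.permutation(n_fr)[: N * M]
    return [sorted(int(j) for j in idx[i * M : (i + 1) * M]) for i in range(N)]


def run_mcs(
    evaluator: Callable[[dict[str, float], list[list[int]] | None], float],
    cfg: McsConfig,
    max_failure_rate: float = 0.05,
) -> McsResult:
    """Re-evaluate a parameter pipeline under input and frame randomization.

    ``evaluator(params, groups)`` must be deterministic given its inputs;
    ``groups`` is None when frame resampling is disabled.  Iterations that
    raise are skipped and counted; more than ``max_failure_rate`` failures
    abort the simulation.
    """
    rng = np.random.default_rng(cfg.seed)
    values: list[float] = []
    n_failed = 0
    for _ in range(cfg.iterations):
        params = sample_inputs(cfg.specs, rng)
        groups = resample_frames(cfg.n_fr, cfg.N, cfg.M, rng) if cfg.resample else None
        try:
            values.append(float(evaluator(params, groups)))
        except Exception:  # noqa: BLE001 - any pipeline failure counts as a miss
            n_failed += 1
    if n_failed > max_failure_rate * cfg.iterations:
        raise McsError(f"{n_failed}/{cfg.iterations} iterations failed")
    arr = np.asarray(values)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return McsResult(sd_mcs=sd, values=arr, n_failed=n_failed)


def combine_sd(sd_rep: float, sd_mcs: float) -> float:
    """Combine repeatability and method SDs by root-sum-square."""
    if sd_rep < 0 or sd_mcs < 0:
        raise ParameterError("standard deviations must be >= 0")
    return math.hypot(sd_rep, sd_mcs)
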
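"""Reference QA survey: published results for three commercial US systems.

A published benchmark survey ran the full protocol on three brand-new
diagnostic ultrasound systems, each with a phased and a convex array
probe, in two configuration settings (A: vendor-recommended presets;
B: pre/post-processing reduced) at three phantom flow regimes.  The
reported per-parameter means and SDs are bundled here as tidy DataFrames:
they serve as worked inputs for the scoring stage (composite-index
computation from already-estimated parameters) and as a comparison point
for new measurements.

Raw parameters (inputs to normalization):

* blind angle BA (degrees), registration error RE (%), velocity
  sensitivity AMVS and accuracy VeMeA (dimensionless) per flow regime
  (QL / QM / QH);
* temporal resolution TR per color line-density setting (LDL / LDM / LDH).

Normalized scores and composite areas, as printed in the survey, are in
:func:`normalized_scores`; radar diagrams use the high-flow regime for
phased probes and the medium regime for convex probes, with TR at medium
line density in both cases.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "blind_angle_results",
    "registration_error_results",
    "amvs_results",
    "vemea_results",
    "temporal_resolution_results",
    "normalized_scores",
    "FLOW_REGIMES",
    "KIVIAT_REGIME",
]

SYSTEMS = (1, 2, 3)
CONFIGS = ("A", "B")
PROBES = ("phased", "convex")

#: Phantom flow-rate settings (mL/s) per QA parameter and regime.
FLOW_REGIMES = {
    "blind_angle": {"QL": 2.0, "QM": 6.0, "QH": 10.0},
    "registration_error": {"QL": 2.0, "QM": 6.0, "QH": 10.0},
    "amvs": {"QL": (2.5, 4.0), "QM": (7.0, 8.5), "QH": (10.0, 11.5)},
    "vemea": {"QL": 2.5, "QM": 7.0, "QH": 11.5},
    "temporal_resolution": {"QM": 6.0},
}

#: Regime feeding the radar diagram, per probe model (TR always at LDM).
KIVIAT_REGIME = {"phased": "QH", "convex": "QM"}


def _table(rows: dict, level_name: str) -> pd.DataFrame:
    """rows: {(probe, config, level): [(mean, sd) x systems 1..3]} -> tidy frame."""
    recs = []
    for (probe, config, level), cells in rows.items():
        for system, (mean, sd) in zip(SYSTEMS, cells):
            recs.append(
                {
                    "probe": probe,
                    "configuration": config,
                    level_name: level,
                    "system": system,
                    "mean": mean,
                    "sd": sd,
                }
            )
    return pd.DataFrame.from_records(recs)


def blind_angle_results() -> pd.DataFrame:
    """Blind angle BA (degrees), mean +- SD."""
    return _table(
        {
            ("phased", "A", "QL"): [(15.7, 2.1), (17.9, 1.6), (6.9, 2.1)],
            ("phased", "A", "QM"): [(9.8, 2.5), (21.6, 1.6), (12.8, 2.4)],
            ("phased", "A", "QH"): [(2.0, 1.1), (2.0, 1.2), (5.6, 1.2)],
            ("phased", "B", "QL"): [(15.4, 2.3), (19.2, 2.0), (11.1, 2.6)],
            ("phased", "B", "QM"): [(12.0, 2.5), (18.1, 2.1), (13.3, 2.5)],
            ("phased", "B", "QH"): [(0.5, 0.4), (7.7, 2.4), (7.4, 2.6)],
            ("convex", "A", "QL"): [(36.0, 3.0), (30.0, 5.0), (30.0, 6.0)],
            ("convex", "A", "QM"): [(16.1, 2.7), (36.8, 2.6), (25.0, 6.0)],
            ("convex", "A", "QH"): [(5.6, 1.2), (9.6, 2.8), (27.0, 5.0)],
            ("convex", "B", "QL"): [(20.0, 3.0), (11.0, 3.0), (10.0, 4.0)],
            ("convex", "B", "QM"): [(13.1, 2.1), (6.2, 2.6), (17.0, 5.0)],
            ("convex", "B", "QH"): [(4.1, 1.3), (2.0, 1.3), (28.0, 5.0)],
        },
        "regime",
    )


def registration_error_results() -> pd.DataFrame:
    """Percentage registration error RE (%), mean +- SD."""
    return _table(
        {
            ("phased", "A", "QL"): [(3.2, 1.9), (3.3, 1.2), (12.0, 8.0)],
            ("phased", "A", "QM"): [(9.4, 2.9), (25.0, 14.0), (13.0, 6.0)],
            ("phased", "A", "QH"): [(20.0, 5.0), (34.0, 6.0), (27.0, 3.0)],
            ("phased", "B", "QL"): [(6.2, 2.1), (12.0, 2.8), (7.9, 2.3)],
            ("phased", "B", "QM"): [(15.0, 3.0), (33.0, 12.0), (28.0, 7.0)],
            ("phased", "B", "QH"): [(18.0, 5.0), (55.1, 3.2), (48.0, 4.0)],
            ("convex", "A", "QL"): [(25.2, 2.2), (15.3, 0.4), (4.8, 1.4)],
            ("convex", "A", "QM"): [(36.0, 5.0), (32.0, 6.0), (3.2, 1.4)],
            ("convex", "A", "QH"): [(34.3, 1.7), (20.0, 3.0), (23.0, 3.0)],
            ("convex", "B", "QL"): [(22.3, 1.4), (12.6, 0.9), (15.0, 2.8)],
            ("convex", "B", "QM"): [(20.0, 3.0), (32.0, 7.0), (25.0, 7.0)],
            ("convex", "B", "QH"): [(36.4, 1.8), (16.0, 3.0), (30.0, 7.0)],
        },
        "regime",
    )


def amvs_results() -> pd.DataFrame:
    """Average maximum velocity sensitivity AMVS, mean +- SD."""
    return _table(
        {
            ("phased", "A", "QL"): [(0.44, 0.12), (0.55, 0.15), (0.44, 0.12)],
            ("phased", "A", "QM"): [(0.51, 0.21), (0.59, 0.42), (0.29, 0.16)],
            ("phased", "A", "QH"): [(0.50, 0.26), (0.07, 0.20), (0.39, 0.25)],
            ("phased", "B", "QL"): [(0.41, 0.11), (0.55, 0.15), (0.58, 0.15)],
            ("phased", "B", "QM"): [(0.53, 0.21), (0.43, 0.36), (0.39, 0.18)],
            ("phased", "B", "QH"): [(0.48, 0.25), (0.03, 0.14), (0.68, 0.40)],
            ("convex", "A", "QL"): [(0.54, 0.14), (0.62, 0.16), (0.48, 0.12)],
            ("convex", "A", "QM"): [(0.36, 0.18), (0.39, 0.17), (0.45, 0.17)],
            ("convex", "A", "QH"): [(0.33, 0.22), (0.57, 0.27), (0.55, 0.27)],
            ("convex", "B", "QL"): [(0.45, 0.12), (0.60, 0.15), (0.46, 0.12)],
            ("convex", "B", "QM"): [(0.30, 0.17), (0.48, 0.19), (0.48, 0.18)],
            ("convex", "B", "QH"): [(0.33, 0.25), (0.43, 0.31), (0.54, 0.45)],
        },
        "regime",
    )


def vemea_results() -> pd.DataFrame:
    """Velocity measurements accuracy VeMeA, mean +- SD."""
    return _table(
        {
            ("phased", "A", "QL"): [(0.38, 0.07), (0.18, 0.12), (0.38, 0.08)],
            ("phased", "A", "QM"): [(0.50, 0.04), (0.12, 0.07), (0.34, 0.04)],
            ("phased", "A", "QH"): [(0.42, 0.03), (0.14, 0.05), (0.43, 0.04)],
            ("phased", "B", "QL"): [(0.44, 0.06), (0.20, 0.12), (0.17, 0.09)],
            ("phased", "B", "QM"): [(0.49, 0.04), (0.25, 0.07), (0.33, 0.04)],
            ("phased", "B", "QH"): [(0.47, 0.03), (0.32, 0.07), (0.49, 0.04)],
            ("convex", "A", "QL"): [(0.24, 0.08), (0.05, 0.11), (0.20, 0.08)],
            ("convex", "A", "QM"): [(0.30, 0.04), (0.19, 0.05), (0.25, 0.04)],
            ("convex", "A", "QH"): [(0.39, 0.03), (0.42, 0.04), (0.51, 0.05)],
            ("convex", "B", "QL"): [(0.17, 0.08), (0.09, 0.11), (0.20, 0.08)],
            ("convex", "B", "QM"): [(0.30, 0.04), (0.17, 0.06), (0.29, 0.04)],
            ("convex", "B", "QH"): [(0.33, 0.04), (0.40, 0.04), (0.64, 0.03)],
        },
        "regime",
    )


def temporal_resolution_results() -> pd.DataFrame:
    """Temporal resolution TR per line-density setting, mean +- SD."""
    return _table(
        {
            ("phased", "A", "LDL"): [(0.10, 0.01), (0.10, 0.01), (0.07, 0.01)],
            ("phased", "A", "LDM"): [(0.08, 0.01), (0.09, 0.01), (0.06, 0.01)],
            ("phased", "A", "LDH"): [(0.06, 0.01), (0.08, 0.01), (0.05, 0.01)],
            ("phased", "B", "LDL"): [(0.17, 0.01), (0.12, 0.01), (0.08, 0.01)],
            ("phased", "B", "LDM"): [(0.14, 0.01), (0.10, 0.01), (0.06, 0.01)],
            ("phased", "B", "LDH"): [(0.11, 0.01), (0.09, 0.01), (0.06, 0.01)],
            ("convex", "A", "LDL"): [(0.10, 0.01), (0.18, 0.02), (0.17, 0.01)],
            ("convex", "A", "LDM"): [(0.09, 0.01), (0.14, 0.02), (0.13, 0.01)],
            ("convex", "A", "LDH"): [(0.07, 0.01), (0.12, 0.02), (0.11, 0.01)],
            ("convex", "B", "LDL"): [(0.14, 0.02), (0.21, 0.02), (0.19, 0.01)],
            ("convex", "B", "LDM"): [(0.12, 0.02), (0.16, 0.02), (0.15, 0.01)],
            ("convex", "B", "LDH"): [(0.10, 0.02), (0.14, 0.02), (0.12, 0.01)],
        },
        "line_density",
    )


def _scores(rows: dict) -> pd.DataFrame:
    recs = []
    for (probe, system, config), vals in rows.items():
        rec = {"probe": probe, "system": system, "configuration": config}
        for name, (m, s) in zip(("BA", "RE", "AMVS", "VeMeA", "TR", "S"), vals):
            rec[f"{name}_star"] = m
            rec[f"{name}_star_sd"] = s
        recs.append(rec)
    return pd.DataFrame.from_records(recs)


def normalized_scores() -> pd.DataFrame:
    """Printed normalized scores and composite areas S* +- sigma.

    Phased rows use the high-flow regime, convex rows the medium one; TR is
    at medium line density for both.
    """
    return _scores(
        {
            ("phased", 1, "A"): [(0.96, 0.02), (0.80, 0.05), (0.50, 0.26),
                                 (0.58, 0.03), (0.40, 0.02), (0.41, 0.07)],
            ("phased", 1, "B"): [(0.99, 0.01), (0.82, 0.05), (0.48, 0.25),
                                 (0.53, 0.03), (0.53, 0.02), (0.45, 0.07)],
            ("phased", 2, "A"): [(0.95, 0.03), (0.66, 0.06), (0.07, 0.20),
                                 (0.86, 0.05), (0.42, 0.02), (0.33, 0.04)],
            ("phased", 2, "B"): [(0.83, 0.05), (0.45, 0.03), (0.03, 0.14),
                                 (0.68, 0.07), (0.45, 0.02), (0.23, 0.03)],
            ("phased", 3, "A"): [(0.86, 0.03), (0.73, 0.03), (0.39, 0.25),
                                 (0.57, 0.04), (0.35, 0.03), (0.33, 0.06)],
            ("phased", 3, "B"): [(0.84, 0.06), (0.52, 0.04), (0.68, 0.40),
                                 (0.51, 0.04), (0.35, 0.03), (0.32, 0.08)],
            ("convex", 1, "A"): [(0.64, 0.06), (0.64, 0.05), (0.36, 0.18),
                                 (0.70, 0.04), (0.42, 0.02), (0.29, 0.05)],
            ("convex", 1, "B"): [(0.71, 0.05), (0.80, 0.03), (0.30, 0.17),
                                 (0.70, 0.04), (0.49, 0.04), (0.34, 0.05)],
            ("convex", 2, "A"): [(0.18, 0.06), (0.68, 0.06), (0.39, 0.17),
                                 (0.81, 0.05), (0.53, 0.04), (0.25, 0.05)],
            ("convex", 2, "B"): [(0.86, 0.06), (0.68, 0.07), (0.48, 0.19),
                                 (0.83, 0.06), (0.56, 0.04), (0.45, 0.06)],
            ("convex", 3, "A"): [(0.44, 0.14), (0.97, 0.01), (0.45, 0.17),
                                 (0.75, 0.04), (0.51, 0.02), (0.36, 0.07)],
            ("convex", 3, "B"): [(0.62, 0.11), (0.75, 0.07), (0.48, 0.18),
                                 (0.71, 0.04), (0.55, 0.02), (0.38, 0.06)],
        }
    )


def raw_parameters(probe: str, system: int, configuration: str) -> dict:
    """The five raw (mean, sd) pairs feeding one radar diagram.

    Uses the regime convention of the survey: high flow for phased probes,
    medium for convex, TR at medium line density.
    """
    regime = KIVIAT_REGIME[probe]

    def cell(df: pd.DataFrame, level_name: str, level: str) -> tuple[float, float]:
        row = df[
            (df["probe"] == probe)
            & (df["system"] == system)
            & (df["configuration"] == configuration)
            & (df[level_name] == level)
        ].iloc[0]
        return float(row["mean"]), float(row["sd"])

    return {
        "BA": cell(blind_angle_results(), "regime", regime),
        "RE": cell(registration_error_results(), "regime", regime),
        "AMVS": cell(amvs_results(), "regime", regime),
        "VeMeA": cell(vemea_results(), "regime", regime),
        "TR": cell(temporal_resolution_results(), "line_density", "LDM"),
    }
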
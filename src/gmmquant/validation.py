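"""Method-validation metrics: precision, recovery, matrix effect, LOD/LOQ.

Implements the bioanalytical validation suite applied to the panel:
intra-/inter-day precision as %RSD of replicate peak areas (acceptance
<= 20 %), spike recovery as pre-/post-spiked concentration ratio (FDA range
80-120 %, boundaries inclusive), matrix effect as the ratio of matrix-matched
to neat-solvent calibration slopes, and per-analyte LOD/LOQ carried over from
the calibration module.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve
from .panel import PanelConfig

__all__ = [
    "precision_rsd",
    "recovery_percent",
    "matrix_effect_percent",
    "build_validation_report",
    "RSD_LIMIT",
    "RECOVERY_RANGE",
]

RSD_LIMIT = 20.0          # % — flagged when strictly greater
RECOVERY_RANGE = (80.0, 120.0)  # % — closed interval, flagged outside


def precision_rsd(values: Sequence[float]) -> float:
    """Percent relative standard deviation of replicate measurements.

    100 x sample (n-1) standard deviation / mean. Requires >= 2 values; a
    zero mean leaves the statistic undefined (NaN).
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError("precision needs at least 2 replicate values")
    mean = arr.mean()
    if mean == 0:
        return float("nan")
    return float(100.0 * arr.std(ddof=1) / mean)


def recovery_percent(pre_spiked: float, post_spiked: float) -> float:
    """Spike recovery: pre-spiked / post-spiked concentration x 100."""
    if post_spiked <= 0:
        return float("nan")
    return 100.0 * pre_spiked / post_spiked


def matrix_effect_percent(slope_matrix: float, slope_neat: float) -> float:
    """Matrix effect: matrix-matched slope / neat-solvent slope x 100."""
    if slope_neat <= 0:
        return float("nan")
    return 100.0 * slope_matrix / slope_neat


def _rsd_or_nan(values: np.ndarray) -> float:
    values = values[np.isfinite(values)]
    if values.size < 2:
        return float("nan")
    return precision_rsd(values)


def build_validation_report(
    matrix_curves: Mapping[tuple[str, str], CalibrationCurve],
    neat_curves: Mapping[str, CalibrationCurve],
    spike_experiments: pd.DataFrame,
    replicate_runs: pd.DataFrame,
    panel: PanelConfig,
    rt_runs: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Assemble the per-analyte x matrix validation table.

    Parameters
    ----------
    matrix_curves
        Matrix-matched calibration curves keyed (matrix, analyte).
    neat_curves
        Neat-solvent curves keyed by analyte id (for matrix effect).
    spike_experiments
        Long table with analyte_id, matrix, pre_spiked, post_spiked (uM).
    replicate_runs
        Peak table of replicate injections with a ``day`` label; intra-day
        precision uses the first day's replicates, inter-day all days.
    rt_runs
        Optional retention-time replicates (same layout, column ``rt``);
        retention-time %RSD columns are emitted only when provided.

    One row is emitted per quantified analyte x matrix even when data are
    missing, with a ``coverage`` flag listing absent metrics.
    """
    matrices = sorted({m for (m, _a) in matrix_curves})
    rows = []
    for a in panel.quantified:
        for matrix in matrices:
            curve = matrix_curves.get((matrix, a.id))
            flags: list[str] = []
            row: dict = {"analyte_id": a.id, "matrix": matrix}

            rep = replicate_runs[
                (replicate_runs["analyte_id"] == a.id)
                & (replicate_runs["matrix"] == matrix)
            ]
            if len(rep):
                days = sorted(rep["day"].unique())
                intra = _rsd_or_nan(
                    rep.loc[rep["day"] == days[0], "analyte_area"].to_numpy(float)
                )
                inter = _rsd_or_nan(rep["analyte_area"].to_numpy(float))
            else:
                intra = inter = float("nan")
            row["intra_day_rsd_area"] = intra
            row["inter_day_rsd_area"] = inter
            if np.isnan(intra) or np.isnan(inter):
                flags.append("no_precision_data")
            elif intra > RSD_LIMIT or inter > RSD_LIMIT:
                flags.append("precision_fail")

            if rt_runs is not None:
                rt = rt_runs[
                    (rt_runs["analyte_id"] == a.id) & (rt_runs["matrix"] == matrix)
                ]
                if len(rt):
                    days = sorted(rt["day"].unique())
                    row["intra_day_rsd_rt"] = _rsd_or_nan(
                        rt.loc[rt["day"] == days[0], "rt"].to_numpy(float)
                    )
                    row["inter_day_rsd_rt"] = _rsd_or_nan(rt["rt"].to_numpy(float))

            spikes = spike_experiments[
                (spike_experiments["analyte_id"] == a.id)
                & (spike_experiments["matrix"] == matrix)
            ]
            if len(spikes):
                rec = recovery_percent(
                    spikes["pre_spiked"].mean(), spikes["post_spiked"].mean()
                )
            else:
                rec = float("nan")
                flags.append("no_recovery_data")
            row["recovery"] = rec
            if np.isfinite(rec) and not (
                RECOVERY_RANGE[0] <= rec <= RECOVERY_RANGE[1]
            ):
                flags.append("recovery_out_of_range")

            neat = neat_curves.get(a.id)
            if curve is not None and curve.ok and neat is not None and neat.ok:
                row["matrix_effect"] = matrix_effect_percent(
                    curve.slope, neat.slope
                )
            else:
                row["matrix_effect"] = float("nan")
                flags.append("no_matrix_effect_data")

            if curve is not None and curve.ok:
                row["lod"] = curve.lod
                row["loq"] = curve.loq
                row["r_squared"] = curve.r_squared
                if not curve.linearity_ok:
                    flags.append("curve_fail")
            else:
                row["lod"] = row["loq"] = row["r_squared"] = float("nan")
                flags.append("curve_fail")

            row["flags"] = ";".join(flags)
            rows.append(row)
    return pd.DataFrame(rows)
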
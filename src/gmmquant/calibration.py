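"""Matrix-matched calibration, back-calculation and unit conversion.

Quantification follows the standard stable-isotope-dilution scheme: the
response ratio (analyte peak area / internal-standard peak area) of
matrix-matched standards is regressed on nominal concentration with
configurable weighting (default 1/x), limits of detection and quantification
are estimated from the low-concentration residual standard deviation as
3.3*s/slope and 10*s/slope, sample extracts are back-calculated through the
curve with dilution selection across each sample's serial-dilution series,
and extract concentrations are converted to specimen units (plasma uM,
feces umol/g) through the preparation constants.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .panel import PanelConfig
from .simulate import PREP_FACTOR

__all__ = [
    "CalibrationCurve",
    "fit_calibration",
    "estimate_lod_loq",
    "fit_all_curves",
    "back_calculate",
    "back_calculate_table",
    "select_dilution",
    "quantify",
    "to_specimen_units",
    "curves_to_frame",
]

#: Cell status labels used throughout quantification and QC.
MEASURED = "measured"
CENSORED = "censored"
ABSENT = "absent"
IMPUTED_MIN = "imputed_min"
IMPUTED_MEDIAN = "imputed_median"


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted response-ratio line for one analyte in one matrix."""

    analyte_id: str
    matrix: str
    slope: float
    intercept: float
    r_squared: float
    lod: float
    loq: float
    n_points: int
    weighting: str
    cal_low: float
    cal_high: float
    ok: bool = True
    failure: str = ""

    @property
    def linearity_ok(self) -> bool:
        """Acceptance rule R^2 > 0.99 for a retained curve."""
        return self.ok and self.r_squared > 0.99


def _weights(x: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "1/x":
        return 1.0 / x
    if weighting == "1/x^2":
        return 1.0 / x**2
    if weighting in ("none", "1"):
        return np.ones_like(x)
    raise ValueError(f"unknown weighting {weighting!r}")


def _failed(analyte_id: str, matrix: str, weighting: str, reason: str) -> CalibrationCurve:
    return CalibrationCurve(
        analyte_id, matrix, np.nan, np.nan, np.nan, np.nan, np.nan,
        0, weighting, np.nan, np.nan, ok=False, failure=reason,
    )


def fit_calibration(
    standards: pd.DataFrame, weighting: str = "1/x"
) -> CalibrationCurve:
    """Least-squares line of response ratio on nominal concentration.

    ``standards`` holds the peak records of one analyte x matrix with
    ``role == "standard"``.  Censored (missing-area) records are dropped;
    fewer than five distinct usable levels is a calibration failure, returned
    as a flagged curve rather than raised, so one failing analyte never
    aborts a run.  R^2 is computed on the fitted (weighted) scale.
    """
    analyte_id = str(standards["analyte_id"].iloc[0])
    matrix = str(standards["matrix"].iloc[0])
    usable = standards.dropna(subset=["analyte_area", "intstd_area"])
    usable = usable[usable["intstd_area"] > 0]
    levels = usable["nominal_conc"].dropna().unique()
    if len(levels) < 5:
        return _failed(analyte_id, matrix, weighting, "fewer than 5 usable levels")
    x = usable["nominal_conc"].to_numpy(dtype=float)
    y = (usable["analyte_area"] / usable["intstd_area"]).to_numpy(dtype=float)
    w = _weights(x, weighting)
    slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
    yhat = slope * x + intercept
    ybar = np.average(y, weights=w)
    ss_res = np.sum(w * (y - yhat) ** 2)
    ss_tot = np.sum(w * (y - ybar) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    curve = CalibrationCurve(
        analyte_id=analyte_id,
        matrix=matrix,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        lod=np.nan,
        loq=np.nan,
        n_points=len(levels),
        weighting=weighting,
        cal_low=float(levels.min()),
        cal_high=float(levels.max()),
        ok=slope > 0,
        failure="" if slope > 0 else "non-positive slope",
    )
    if curve.ok:
        lod, loq = estimate_lod_loq(curve, usable)
        curve = replace(curve, lod=lod, loq=loq)
    return curve


def estimate_lod_loq(
    curve: CalibrationCurve,
    standards: pd.DataFrame,
    n_low_levels: int = 6,
    sd_factor_lod: float = 3.3,
    sd_factor_loq: float = 10.0,
) -> tuple[float, float]:
    """LOD/LOQ from the low-concentration residual standard deviation.

    Default (ICH-style) estimator: s is the residual SD of the response
    ratios at the lowest ``n_low_levels`` distinct calibration levels around
    the fitted line; LOD = 3.3*s/|slope|, LOQ = 10*s/|slope|, so
    LOQ/LOD = 10/3.3 identically. A perfect line gives LOD = LOQ = 0.
    """
    if not curve.ok or not np.isfinite(curve.slope) or curve.slope == 0:
        return (np.nan, np.nan)
    usable = standards.dropna(subset=["analyte_area", "intstd_area"])
    levels = np.sort(usable["nominal_conc"].unique())[:n_low_levels]
    low = usable[usable["nominal_conc"].isin(levels)]
    x = low["nominal_conc"].to_numpy(dtype=float)
    y = (low["analyte_area"] / low["intstd_area"]).to_numpy(dtype=float)
    res = y - (curve.slope * x + curve.intercept)
    s = float(np.std(res, ddof=1)) if res.size > 1 else 0.0
    return (
        sd_factor_lod * s / abs(curve.slope),
        sd_factor_loq * s / abs(curve.slope),
    )


def fit_all_curves(
    standards: pd.DataFrame,
    panel: PanelConfig,
    weighting: str = "1/x",
) -> dict[tuple[str, str], CalibrationCurve]:
    """Fit one curve per (matrix, analyte) present in a standards table."""
    curves: dict[tuple[str, str], CalibrationCurve] = {}
    for (matrix, analyte_id), grp in standards[
        standards["role"] == "standard"
    ].groupby(["matrix", "analyte_id"]):
        curves[(str(matrix), str(analyte_id))] = fit_calibration(grp, weighting)
    return curves


def back_calculate(
    record: Mapping, curve: CalibrationCurve
) -> tuple[float, str]:
    """Back-calculate one peak record through its calibration curve.

    Returns ``(concentration, status)`` where the concentration is the
    dilution-corrected extract concentration (uM) and status is one of
    ``measured``, ``censored`` (below LOQ), ``absent`` (missing analyte
    area), or ``no_curve``.
    """
    if not curve.ok:
        return (np.nan, "no_curve")
    area = record["analyte_area"]
    is_area = record["intstd_area"]
    if area is None or (isinstance(area, float) and np.isnan(area)):
        return (np.nan, ABSENT)
    if is_area is None or not np.isfinite(is_area) or is_area <= 0:
        return (np.nan, ABSENT)
    ratio = area / is_area
    extract = (ratio - curve.intercept) / curve.slope
    dil = float(record["dilution_factor"])
    loq = curve.loq if np.isfinite(curve.loq) else 0.0
    if extract < loq:
        return (np.nan, CENSORED)
    return (extract * dil, MEASURED)


def back_calculate_table(
    peaks: pd.DataFrame,
    curves: Mapping[tuple[str, str], CalibrationCurve],
) -> pd.DataFrame:
    """Vectorised back-calculation of a cohort peak table.

    Adds ``extract_conc`` (at the injected dilution), ``conc`` (dilution
    corrected, neat-extract equivalent) and ``status`` columns.
    """
    out = peaks.copy()
    conc = np.full(len(out), np.nan)
    undil = np.full(len(out), np.nan)
    status = np.array([ABSENT] * len(out), dtype=object)
    for (matrix, analyte_id), idx in out.groupby(
        ["matrix", "analyte_id"]
    ).indices.items():
        curve = curves.get((matrix, analyte_id))
        if curve is None or not curve.ok:
            status[idx] = "no_curve"
            continue
        sub = out.iloc[idx]
        ratio = sub["analyte_area"].to_numpy() / sub["intstd_area"].to_numpy()
        extract = (ratio - curve.intercept) / curve.slope
        dil = sub["dilution_factor"].to_numpy(dtype=float)
        loq = curve.loq if np.isfinite(curve.loq) else 0.0
        missing = ~np.isfinite(ratio)
        censored = np.isfinite(extract) & (extract < loq)
        ok = np.isfinite(extract) & ~censored
        status[idx[missing]] = ABSENT
        status[idx[censored]] = CENSORED
        status[idx[ok]] = MEASURED
        undil[idx] = extract
        conc[idx[ok]] = extract[ok] * dil[ok]
    out["undiluted_conc"] = undil
    out["conc"] = conc
    out["status"] = status
    return out


def select_dilution(
    candidates: pd.DataFrame, curve: CalibrationCurve
) -> tuple[float, str, float]:
    """Pick the reported value from a sample's dilution series.

    Rule: the least-diluted record whose undiluted (in-vial) concentration
    lies within the calibration range wins; if every quantifiable record
    exceeds the range, the most-diluted one is used (extrapolated); if all
    records are censored or missing, the cell is censored/absent.

    Returns ``(value, status, dilution_factor)``.
    """
    cand = candidates.sort_values("dilution_factor")
    in_range = cand[
        (cand["status"] == MEASURED)
        & (cand["undiluted_conc"] >= curve.cal_low)
        & (cand["undiluted_conc"] <= curve.cal_high)
    ]
    if len(in_range):
        row = in_range.iloc[0]
        return (float(row["conc"]), MEASURED, float(row["dilution_factor"]))
    above = cand[
        (cand["status"] == MEASURED) & (cand["undiluted_conc"] > curve.cal_high)
    ]
    if len(above):
        row = above.iloc[-1]
        return (float(row["conc"]), MEASURED, float(row["dilution_factor"]))
    measured = cand[cand["status"] == MEASURED]
    if len(measured):  # quantifiable but below the lowest standard
        row = measured.iloc[0]
        return (float(row["conc"]), MEASURED, float(row["dilution_factor"]))
    if (cand["status"] == CENSORED).any():
        return (np.nan, CENSORED, np.nan)
    return (np.nan, ABSENT, np.nan)


def to_specimen_units(
    extract_conc, matrix: str, prep: Optional[Mapping[str, float]] = None
):
    """Convert a neat-extract concentration (uM) to specimen units.

    Plasma: 100 uL plasma extracted into 1000 uL total -> x10 (uM plasma).
    Feces: 250 mg extracted with 2 mL -> x 0.002 L / 0.25 g = x0.008
    (umol/g). Accepts scalars or arrays.
    """
    prep = dict(prep or PREP_FACTOR)
    if matrix not in prep:
        raise ValueError(f"unknown matrix {matrix!r}")
    if any(v <= 0 for v in prep.values()):
        raise ValueError("preparation constants must be positive")
    return extract_conc * prep[matrix]


def quantify(
    peaks: pd.DataFrame,
    curves: Mapping[tuple[str, str], CalibrationCurve],
    panel: PanelConfig,
    matrix: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Back-calculate a cohort peak table into a samples x analytes matrix.

    Returns ``(values, status)``: specimen-unit concentrations and the
    per-cell status (measured / censored / absent / no_curve) after dilution
    selection.
    """
    sub = peaks[(peaks["matrix"] == matrix) & (peaks["role"] == "cohort")]
    bc = back_calculate_table(sub, curves)
    samples = list(dict.fromkeys(sub["sample_id"]))
    analytes = [a.id for a in panel.quantified]
    values = pd.DataFrame(np.nan, index=samples, columns=analytes)
    status = pd.DataFrame(ABSENT, index=samples, columns=analytes, dtype=object)
    for (sid, analyte_id), grp in bc.groupby(["sample_id", "analyte_id"]):
        curve = curves.get((matrix, analyte_id))
        if curve is None or not curve.ok:
            status.at[sid, analyte_id] = "no_curve"
            continue
        val, st, _ = select_dilution(grp, curve)
        if st == MEASURED:
            values.at[sid, analyte_id] = to_specimen_units(val, matrix)
        status.at[sid, analyte_id] = st
    return values, status


def curves_to_frame(
    curves: Mapping[tuple[str, str], CalibrationCurve]
) -> pd.DataFrame:
    """Export fitted curves as a flat table."""
    return pd.DataFrame(
        [
            {
                "matrix": c.matrix,
                "analyte_id": c.analyte_id,
                "slope": c.slope,
                "intercept": c.intercept,
                "r_squared": c.r_squared,
                "lod": c.lod,
                "loq": c.loq,
                "n_points": c.n_points,
                "weighting": c.weighting,
                "ok": c.ok,
                "linearity_ok": c.linearity_ok,
                "failure": c.failure,
            }
            for c in curves.values()
        ]
    )
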
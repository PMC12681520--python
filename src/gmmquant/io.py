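"""Readers, writers and run configuration.

All tables move as delimited text with documented headers; the peak-table
schema mirrors a vendor-style export of integrated MRM areas (one row per
sample x analyte x dilution). Missing areas stay missing (empty field), never
zero.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .panel import PanelConfig

__all__ = [
    "PEAK_TABLE_COLUMNS",
    "PeakTableError",
    "read_peak_table",
    "write_peak_table",
    "read_cohort_table",
    "write_cohort_table",
    "RunConfig",
]

PEAK_TABLE_COLUMNS = [
    "sample_id",
    "analyte_id",
    "matrix",
    "dilution_factor",
    "analyte_area",
    "intstd_area",
    "batch",
    "day",
    "role",
    "nominal_conc",
]

_ROLES = {"standard", "qc_pool", "cohort"}


class PeakTableError(ValueError):
    """Malformed peak table input."""


def read_peak_table(path, panel: Optional[PanelConfig] = None) -> pd.DataFrame:
    """Read a delimited peak table, validating schema and analyte ids.

    The delimiter is sniffed (comma or tab) and surrounding whitespace and
    quoting dialects are tolerated. Unknown analyte ids (when a panel is
    given), negative areas and unknown roles raise :class:`PeakTableError`
    naming the offending row; missing areas are preserved as missing.
    """
    df = pd.read_csv(path, sep=None, engine="python", skipinitialspace=True)
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise PeakTableError(f"peak table missing columns: {missing}")
    df = df[PEAK_TABLE_COLUMNS].copy()
    for col in ("sample_id", "analyte_id", "matrix", "batch", "day", "role"):
        df[col] = df[col].astype(str).str.strip()
    for col in ("dilution_factor", "analyte_area", "intstd_area", "nominal_conc"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise PeakTableError(f"non-numeric value in column {col!r}: {exc}") from exc
    bad = df.index[(df["analyte_area"] < 0) | (df["intstd_area"] < 0)]
    if len(bad):
        raise PeakTableError(
            f"negative peak area at data row(s) {list(bad[:5] + 2)}"
        )
    bad = df.index[~df["role"].isin(_ROLES)]
    if len(bad):
        raise PeakTableError(
            f"unknown role {df.loc[bad[0], 'role']!r} at data row {bad[0] + 2}"
        )
    if (df["dilution_factor"] < 1).any():
        raise PeakTableError("dilution_factor must be >= 1")
    std_missing = (df["role"] == "standard") & df["nominal_conc"].isna()
    if std_missing.any():
        raise PeakTableError(
            f"standard record without nominal_conc at data row "
            f"{df.index[std_missing][0] + 2}"
        )
    if panel is not None:
        known = {a.id for a in panel.analytes}
        unknown = sorted(set(df["analyte_id"]) - known)
        if unknown:
            raise PeakTableError(f"unknown analyte id(s): {unknown}")
    return df


def write_peak_table(peaks: pd.DataFrame, path) -> None:
    peaks.to_csv(path, index=False)


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", skipinitialspace=True)
    required = {"subject_id", "group", "age", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise PeakTableError(f"cohort table missing columns: {sorted(missing)}")
    if "comorbidity" not in df.columns:
        df["comorbidity"] = ""
    df["comorbidity"] = df["comorbidity"].fillna("")
    return df


def write_cohort_table(subjects: pd.DataFrame, path) -> None:
    subjects.to_csv(path, index=False)


class RunConfig(BaseModel):
    """End-to-end pipeline configuration.

    In ``synthetic`` mode the generator produces cohort, standards and peak
    tables from ``seed``; in ``peak_table`` mode the referenced files are
    read instead.
    """

    model_config = ConfigDict(frozen=True)

    input_mode: str = "synthetic"
    panel_path: Optional[str] = None
    seed: int = 0
    matrices: tuple[str, ...] = ("plasma", "feces")
    output_dir: str = "gmmquant-run"
    # peak_table mode inputs
    peak_table_paths: dict[str, str] = {}
    standards_paths: dict[str, str] = {}
    cohort_path: Optional[str] = None
    # cascade / statistics options
    detection_threshold: float = 0.8
    weighting: str = "1/x"
    n_calibration_points: int = 10
    calibration_replicates: int = 3
    log_transform: bool = True
    alpha: float = 0.05
    adjust_method: str = "fdr_bh"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.input_mode not in {"synthetic", "peak_table"}:
            raise ValueError(f"unknown input mode {self.input_mode!r}")
        known = {"plasma", "feces"}
        unknown = set(self.matrices) - known
        if unknown:
            raise ValueError(f"unknown matrix {sorted(unknown)[0]!r}")
        if not 0 < self.detection_threshold <= 1:
            raise ValueError("detection_threshold must be in (0, 1]")
        if self.input_mode == "peak_table":
            for m in self.matrices:
                for mapping, kind in (
                    (self.peak_table_paths, "peak table"),
                    (self.standards_paths, "standards"),
                ):
                    p = mapping.get(m)
                    if p is None or not Path(p).exists():
                        raise ValueError(f"missing {kind} path for matrix {m!r}")
            if self.cohort_path is None or not Path(self.cohort_path).exists():
                raise ValueError("missing cohort table path")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})
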
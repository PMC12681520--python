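"""Shared fixtures: panel, generator models, small cohorts, matrix builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gmmquant import qc
from gmmquant.panel import default_panel
from gmmquant.simulate import (
    CohortSpec,
    default_concentration_model,
    default_instrument_model,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def instrument(panel):
    return default_instrument_model(panel)


@pytest.fixture(scope="session")
def nf_instrument(instrument):
    """Noise-free instrument: no variance, censoring or suppression."""
    return instrument.noise_free()


@pytest.fixture(scope="session")
def conc_model(panel):
    return default_concentration_model(panel)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(CohortSpec(n_hc=8, n_pd=6, seed=11))


@pytest.fixture(scope="session")
def full_cohort():
    """Study-sized cohort: 60 HC vs 31 PD."""
    return simulate_cohort(CohortSpec(seed=5))


def build_quant_matrix(
    values: dict[str, list[float]],
    groups: list[str],
    provenance: dict[str, list[str]] | None = None,
    matrix: str = "plasma",
) -> qc.QuantMatrix:
    """Hand-build a QuantMatrix from per-entity value lists."""
    idx = [f"S{i + 1:02d}" for i in range(len(groups))]
    vals = pd.DataFrame(values, index=idx, dtype=float)
    if provenance is None:
        prov = vals.copy().astype(object)
        prov[:] = "measured"
        prov = prov.mask(vals.isna(), "censored")
    else:
        prov = pd.DataFrame(provenance, index=idx, dtype=object)
    meta = pd.DataFrame({"group": groups}, index=idx)
    return qc.QuantMatrix(vals, prov, meta, matrix)


@pytest.fixture
def make_qm():
    return build_quant_matrix


def standards_frame(
    levels,
    ratios,
    analyte_id: str = "X",
    matrix: str = "plasma",
    intstd_area: float = 1.0,
) -> pd.DataFrame:
    """Minimal standards table with analyte_area = ratio (IntStd area 1)."""
    rows = []
    for level, ratio in zip(levels, ratios):
        rows.append(
            {
                "sample_id": f"std-{level}",
                "analyte_id": analyte_id,
                "matrix": matrix,
                "dilution_factor": 1.0,
                "analyte_area": np.nan if ratio is None else ratio * intstd_area,
                "intstd_area": intstd_area,
                "batch": "cal",
                "day": "d1",
                "role": "standard",
                "nominal_conc": level,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def make_standards():
    return standards_frame
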
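"""QC cascade: detection filtering, imputation, IntStd gating, collapsing.

Turns back-calculated concentrations into the analysis-ready matrix through a
fixed, audited sequence of rules:

1. exclusions (column-accumulating analytes never enter the matrix);
2. conjugate collapsing (co-eluting taurine-/glycine-conjugated bile acids
   summed into two reporting groups);
3. detection-rate filter (an entity is kept only if detected in >= 80 % of
   samples within *every* group; "fewer than 80 %" excludes, exactly 80 %
   is kept);
4. group-minimum imputation of remaining censored/absent cells;
5. internal-standard recovery gate (samples whose back-calculated IntStd
   concentration falls strictly below 80 % or strictly above 120 % of the
   nominal spike are flagged per ESI mode);
6. group-median imputation of every cell of a flagged sample, with the donor
   pool restricted to measured values from unflagged samples of the same
   clinical group.

Each rule appends an audit entry with counts so the cascade is reproducible
from the log. Re-running the cascade on its own output is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .calibration import (
    ABSENT,
    CENSORED,
    IMPUTED_MEDIAN,
    IMPUTED_MIN,
    MEASURED,
    CalibrationCurve,
    quantify,
)
from .panel import PanelConfig, resolve_quant_groups

__all__ = [
    "QuantMatrix",
    "detection_rate_filter",
    "impute_group_minimum",
    "intstd_reference_from_standards",
    "gate_internal_standard",
    "impute_group_median_flagged",
    "collapse_conjugates",
    "run_cascade",
]

_PROVENANCE_RANK = {
    MEASURED: 0,
    IMPUTED_MIN: 1,
    IMPUTED_MEDIAN: 2,
    CENSORED: 3,
    ABSENT: 4,
    "no_curve": 5,
}

#: Provenances that count as "detected / has a value".
_VALUED = {MEASURED, IMPUTED_MIN, IMPUTED_MEDIAN}


class CascadeError(ValueError):
    """Unrecoverable state in the QC cascade (e.g. an empty group)."""


@dataclass
class QuantMatrix:
    """Samples x reporting-entities concentration matrix with provenance.

    ``values`` and ``provenance`` share shape and labels; ``sample_meta`` is
    indexed by sample id and carries at least a ``group`` column; ``audit``
    is the ordered log of applied rules with counts.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame
    sample_meta: pd.DataFrame
    matrix: str
    audit: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.provenance.index) or not list(
            self.values.columns
        ) == list(self.provenance.columns):
            raise ValueError("values and provenance must share labels")
        unknown = set(np.unique(self.provenance.to_numpy(dtype=object))) - set(
            _PROVENANCE_RANK
        )
        if unknown:
            raise ValueError(f"unknown provenance labels: {sorted(unknown)}")
        if "group" not in self.sample_meta.columns:
            raise ValueError("sample_meta needs a 'group' column")

    def _copy(self) -> "QuantMatrix":
        return QuantMatrix(
            self.values.copy(),
            self.provenance.copy(),
            self.sample_meta,
            self.matrix,
            list(self.audit),
        )

    def log(self, rule: str, **counts) -> None:
        self.audit.append({"rule": rule, **counts})

    def groups(self) -> pd.Series:
        return self.sample_meta.loc[self.values.index, "group"]

    @property
    def entities(self) -> list[str]:
        return list(self.values.columns)

    def provenance_counts(self) -> dict[str, int]:
        flat = self.provenance.to_numpy(dtype=object).ravel()
        return {k: int((flat == k).sum()) for k in _PROVENANCE_RANK if k in flat}

    def is_complete(self) -> bool:
        """True when every retained cell holds a value."""
        return bool(
            self.provenance.isin(_VALUED).all().all()
            and np.isfinite(self.values.to_numpy()).all()
        )


def _check_groups(qm: QuantMatrix) -> pd.Series:
    groups = qm.groups()
    if groups.isna().any():
        raise CascadeError("every sample must carry a group label")
    for g, cnt in groups.value_counts().items():
        if cnt == 0:  # pragma: no cover - value_counts never yields 0
            raise CascadeError(f"group {g!r} is empty")
    return groups


def detection_rate_filter(qm: QuantMatrix, threshold: float = 0.8) -> QuantMatrix:
    """Retain an entity iff its detection rate >= threshold in every group.

    Detection means the cell holds a value (measured or previously imputed);
    censored and absent cells are undetected. The boundary is inclusive:
    exactly 80 % detected is retained.
    """
    groups = _check_groups(qm)
    if groups.nunique() == 0:
        raise CascadeError("no groups present")
    detected = qm.provenance.isin(_VALUED)
    rate = detected.groupby(groups).mean()
    keep = (rate >= threshold).all(axis=0)
    kept = [c for c in qm.entities if keep[c]]
    dropped = [c for c in qm.entities if not keep[c]]
    out = QuantMatrix(
        qm.values[kept],
        qm.provenance[kept],
        qm.sample_meta,
        qm.matrix,
        list(qm.audit),
    )
    out.log(
        "detection_rate_filter",
        threshold=threshold,
        retained=len(kept),
        dropped=len(dropped),
        dropped_entities=dropped,
    )
    return out


def impute_group_minimum(qm: QuantMatrix) -> QuantMatrix:
    """Impute censored/absent cells with the group minimum of measured values."""
    groups = _check_groups(qm)
    out = qm._copy()
    n_imputed = 0
    for entity in out.entities:
        prov = out.provenance[entity]
        missing = prov.isin({CENSORED, ABSENT, "no_curve"})
        if not missing.any():
            continue
        measured = out.values[entity].where(prov == MEASURED)
        for g in groups.unique():
            in_g = groups == g
            cells = missing & in_g
            if not cells.any():
                continue
            donor = measured[in_g].dropna()
            if donor.empty:
                raise CascadeError(
                    f"no measured donor values for entity {entity!r} in group "
                    f"{g!r}; run the detection filter first"
                )
            out.values.loc[cells, entity] = donor.min()
            out.provenance.loc[cells, entity] = IMPUTED_MIN
            n_imputed += int(cells.sum())
    out.log("impute_group_minimum", cells_imputed=n_imputed)
    return out


def intstd_reference_from_standards(
    standards: pd.DataFrame, panel: PanelConfig
) -> dict[str, float]:
    """Expected IntStd peak area per ESI mode, from calibration standards.

    The IntStd is spiked at one nominal level in every injection, so its
    calibration degenerates to a single-point response factor: the mean
    IntStd area across standards corresponds to 100 % recovery of the
    nominal concentration.
    """
    mode_of = {a.id: a.esi_mode for a in panel.analytes}
    ref: dict[str, float] = {}
    std = standards[standards["role"] == "standard"]
    modes = std["analyte_id"].map(mode_of)
    for mode in ("positive", "negative"):
        areas = std.loc[modes == mode, "intstd_area"].dropna()
        if len(areas):
            ref[mode] = float(areas.mean())
    return ref


def gate_internal_standard(
    peaks: pd.DataFrame,
    panel: PanelConfig,
    reference: Mapping[str, float],
    low: float = 80.0,
    high: float = 120.0,
) -> dict[str, dict[str, str]]:
    """Flag samples whose back-calculated IntStd recovery leaves [80, 120] %.

    Per sample and ESI mode, recovery = mean observed IntStd area over the
    sample's injections divided by the reference area (itself equivalent to
    the nominal spike), x100.  Bounds are strict: exactly 80 % or 120 % is
    not flagged.  Samples with no IntStd area at all are flagged with reason
    ``missing_intstd``.

    Returns mode -> {sample_id: reason} where reason is ``low``, ``high`` or
    ``missing_intstd``.
    """
    mode_of = {a.id: a.esi_mode for a in panel.analytes}
    cohort = peaks[peaks["role"] == "cohort"].copy()
    cohort["esi_mode"] = cohort["analyte_id"].map(mode_of)
    flagged: dict[str, dict[str, str]] = {"positive": {}, "negative": {}}
    for (sid, mode), grp in cohort.groupby(["sample_id", "esi_mode"]):
        areas = grp["intstd_area"].dropna()
        if areas.empty:
            flagged[mode][sid] = "missing_intstd"
            continue
        if mode not in reference:
            continue
        recovery = 100.0 * areas.mean() / reference[mode]
        if recovery < low:
            flagged[mode][sid] = "low"
        elif recovery > high:
            flagged[mode][sid] = "high"
    return flagged


def impute_group_median_flagged(
    qm: QuantMatrix,
    flagged: Mapping[str, Mapping[str, str]],
    entity_modes: Mapping[str, str],
) -> QuantMatrix:
    """Replace every cell of a flagged sample by the group median.

    A sample flagged in one ESI mode has its cells replaced only for entities
    acquired in that mode. The donor pool is measured values from unflagged
    samples of the same clinical group; a group whose samples are all flagged
    has no donors and is an error.
    """
    groups = _check_groups(qm)
    out = qm._copy()
    n_imputed = 0
    n_overwrote_min = 0
    for entity in out.entities:
        mode = entity_modes.get(entity)
        if mode is None:
            raise CascadeError(f"no ESI mode known for entity {entity!r}")
        bad_ids = set(flagged.get(mode, {})) & set(out.values.index)
        if not bad_ids:
            continue
        is_flagged = out.values.index.isin(bad_ids)
        prov = out.provenance[entity]
        donors_mask = (~is_flagged) & (prov == MEASURED).to_numpy()
        for g in groups.unique():
            in_g = (groups == g).to_numpy()
            cells = in_g & is_flagged
            if not cells.any():
                continue
            donor = out.values[entity].to_numpy()[in_g & donors_mask]
            if donor.size == 0:
                raise CascadeError(
                    f"all samples of group {g!r} flagged for entity {entity!r}; "
                    "no donor values for median imputation"
                )
            prior = out.provenance[entity].to_numpy()[cells]
            n_overwrote_min += int((prior == IMPUTED_MIN).sum())
            n_imputed += int((prior != IMPUTED_MEDIAN).sum())
            out.values.loc[cells, entity] = float(np.median(donor))
            out.provenance.loc[cells, entity] = IMPUTED_MEDIAN
    out.log(
        "impute_group_median_flagged",
        flagged_samples={m: sorted(v) for m, v in flagged.items()},
        cells_imputed=n_imputed,
        overwrote_imputed_min=n_overwrote_min,
    )
    return out


def collapse_conjugates(
    qm: QuantMatrix, groups: Mapping[str, list[str]]
) -> QuantMatrix:
    """Replace conjugate member columns by their summed group column.

    A group cell is the sum of its member cells and is ``measured`` iff all
    members are measured; otherwise it takes the weakest member provenance
    (and no value). Groups whose members are absent from the matrix are
    summed over the present members with a warning; singleton groups are the
    identity.
    """
    import warnings

    values = {}
    prov = {}
    n_collapsed = 0
    for label, members in groups.items():
        present = [m for m in members if m in qm.values.columns]
        if not present:
            # already collapsed (or members never quantified): pass through
            if label in qm.values.columns:
                values[label] = qm.values[label]
                prov[label] = qm.provenance[label]
            continue
        if len(members) == 1:
            values[label] = qm.values[present[0]]
            prov[label] = qm.provenance[present[0]]
            continue
        if len(present) < len(members):
            warnings.warn(
                f"conjugate group {label!r}: members {sorted(set(members) - set(present))} "
                "missing from the matrix; summing over present members",
                stacklevel=2,
            )
        ranks = qm.provenance[present].apply(
            lambda col: col.map(_PROVENANCE_RANK)
        )
        worst = ranks.max(axis=1)
        all_measured = (ranks == _PROVENANCE_RANK[MEASURED]).all(axis=1)
        summed = qm.values[present].sum(axis=1)
        values[label] = summed.where(all_measured)
        inv = {v: k for k, v in _PROVENANCE_RANK.items()}
        prov[label] = worst.map(inv).where(~all_measured, MEASURED)
        n_collapsed += 1
    out = QuantMatrix(
        pd.DataFrame(values, index=qm.values.index),
        pd.DataFrame(prov, index=qm.values.index),
        qm.sample_meta,
        qm.matrix,
        list(qm.audit),
    )
    out.log("collapse_conjugates", groups_collapsed=n_collapsed)
    return out


def run_cascade(
    peaks: pd.DataFrame,
    panel: PanelConfig,
    curves: Mapping[tuple[str, str], CalibrationCurve],
    matrix: str,
    subjects: pd.DataFrame,
    standards: Optional[pd.DataFrame] = None,
    detection_threshold: float = 0.8,
) -> QuantMatrix:
    """Full cascade from a cohort peak table to the analysis-ready matrix."""
    values, status = quantify(peaks, curves, panel, matrix)
    meta = subjects.set_index("subject_id") if "subject_id" in subjects else subjects
    qm = QuantMatrix(values, status, meta, matrix)
    excluded = [a.id for a in panel.targets if a.excluded]
    qm.log("exclusions", excluded_analytes=excluded, n_excluded=len(excluded))

    groups = resolve_quant_groups(panel)
    qm = collapse_conjugates(qm, groups)
    qm = detection_rate_filter(qm, detection_threshold)
    qm = impute_group_minimum(qm)

    if standards is not None:
        reference = intstd_reference_from_standards(standards, panel)
        flagged = gate_internal_standard(peaks, panel, reference)
        mode_of = {a.id: a.esi_mode for a in panel.analytes}
        entity_modes = {
            label: mode_of[members[0]] for label, members in groups.items()
        }
        qm = impute_group_median_flagged(qm, flagged, entity_modes)
    return qm
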
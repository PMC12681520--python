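"""Analyte panel definition and validation.

The panel drives every downstream stage: which compounds are quantified, in
which electrospray-ionisation (ESI) mode each is acquired, which
isotope-labelled internal standard (IntStd) normalises it, how co-eluting
conjugated bile acids are collapsed into reporting groups, and which analytes
are excluded outright (compounds that accumulate on the column).

The shipped default panel covers 17 uremic toxins and 16 bile acids (33
quantification targets, of which GCA, CDCA and GB carry exclusion flags,
leaving 16 UTs + 14 BAs = 30 quantified targets) plus two internal standards:
p-cresol sulfate-d7 for ESI- and glycodeoxycholic acid-d6 for ESI+.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "Analyte",
    "PanelConfig",
    "PanelError",
    "load_panel",
    "default_panel",
    "resolve_quant_groups",
]

EsiMode = Literal["positive", "negative"]
AnalyteClass = Literal["uremic_toxin", "primary_bile_acid", "secondary_bile_acid"]
ConjugateGroup = Literal["taurine_conjugates", "glycine_conjugates", "none"]


class PanelError(ValueError):
    """Configuration error in a panel definition."""


class Analyte(BaseModel):
    """One panel member.

    ``internal_standard`` references the id of an IntStd entry in the same
    panel; it is ``None`` only for IntStd entries themselves.
    ``mrm_transition`` is optional metadata (precursor/product m/z) and is
    never used in computation.
    """

    model_config = ConfigDict(frozen=True)

    id: str
    name: str
    analyte_class: AnalyteClass = Field(alias="class")
    esi_mode: EsiMode
    internal_standard: Optional[str] = None
    is_internal_standard: bool = False
    conjugate_group: ConjugateGroup = "none"
    calibration_range: tuple[float, float] = (0.005, 20.0)
    excluded: bool = False
    excluded_reason: str = ""
    mrm_transition: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "Analyte":
        low, high = self.calibration_range
        if not (0 < low < high):
            raise PanelError(
                f"analyte {self.id!r}: calibration_range must satisfy "
                f"0 < low < high, got {self.calibration_range}"
            )
        if self.excluded and not self.excluded_reason:
            raise PanelError(f"analyte {self.id!r}: excluded without a reason")
        return self


class PanelConfig(BaseModel):
    """A validated analyte panel with dilution schemes and IntStd spikes."""

    model_config = ConfigDict(frozen=True)

    analytes: tuple[Analyte, ...]
    intstd_nominal: dict[EsiMode, float]
    matrices: frozenset[str] = frozenset({"plasma", "feces"})
    dilution_schemes: dict[str, tuple[float, ...]] = {
        "plasma": (1.0, 2.0, 50.0),
        "feces": (1.0, 2.0, 10.0),
    }

    @model_validator(mode="after")
    def _check(self) -> "PanelConfig":
        ids = [a.id for a in self.analytes]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise PanelError(f"duplicate analyte ids: {sorted(dupes)}")
        intstds = {a.id for a in self.analytes if a.is_internal_standard}
        for a in self.analytes:
            if a.is_internal_standard:
                continue
            if a.internal_standard not in intstds:
                raise PanelError(
                    f"analyte {a.id!r}: internal_standard "
                    f"{a.internal_standard!r} is not an IntStd in the panel"
                )
        if set(self.intstd_nominal) != {"positive", "negative"}:
            raise PanelError(
                "intstd_nominal must hold exactly the two ESI modes, got "
                f"{sorted(self.intstd_nominal)}"
            )
        if any(v <= 0 for v in self.intstd_nominal.values()):
            raise PanelError("intstd_nominal concentrations must be positive")
        for matrix, scheme in self.dilution_schemes.items():
            if matrix not in self.matrices:
                raise PanelError(f"dilution scheme for unknown matrix {matrix!r}")
            if not scheme or scheme[0] < 1 or any(
                b <= a for a, b in zip(scheme, scheme[1:])
            ):
                raise PanelError(
                    f"dilution factors for {matrix!r} must be >= 1 and "
                    f"strictly increasing, got {scheme}"
                )
        return self

    # -- convenience views ---------------------------------------------------
    @property
    def internal_standards(self) -> tuple[Analyte, ...]:
        return tuple(a for a in self.analytes if a.is_internal_standard)

    @property
    def targets(self) -> tuple[Analyte, ...]:
        """All quantification targets, including excluded ones."""
        return tuple(a for a in self.analytes if not a.is_internal_standard)

    @property
    def quantified(self) -> tuple[Analyte, ...]:
        """Targets actually quantified (exclusion flags removed)."""
        return tuple(a for a in self.targets if not a.excluded)

    def analyte(self, analyte_id: str) -> Analyte:
        for a in self.analytes:
            if a.id == analyte_id:
                return a
        raise KeyError(analyte_id)

    def intstd_for_mode(self, mode: EsiMode) -> Analyte:
        for a in self.internal_standards:
            if a.esi_mode == mode:
                return a
        raise PanelError(f"no internal standard for ESI mode {mode!r}")

    def summary(self) -> dict:
        """Panel arithmetic, exposed so count discrepancies are auditable."""
        quant = self.quantified
        groups = resolve_quant_groups(self)
        return {
            "n_entries": len(self.analytes),
            "n_internal_standards": len(self.internal_standards),
            "n_targets": len(self.targets),
            "n_excluded": len(self.targets) - len(quant),
            "n_quantified": len(quant),
            "n_uremic_toxins": sum(
                a.analyte_class == "uremic_toxin" for a in quant
            ),
            "n_bile_acids": sum(
                a.analyte_class != "uremic_toxin" for a in quant
            ),
            "n_reporting_entities": len(groups),
        }


def _load_structured(source) -> dict:
    if isinstance(source, dict):
        return source
    if isinstance(source, (str, Path)):
        try:
            is_file = Path(str(source)).is_file()
        except OSError:  # e.g. an inline YAML string too long for a filename
            is_file = False
        text = Path(source).read_text() if is_file else str(source)
        return yaml.safe_load(text)
    return yaml.safe_load(source)


def load_panel(config_source) -> PanelConfig:
    """Parse and validate a panel definition.

    Parameters
    ----------
    config_source
        A path to a YAML/JSON file, a YAML string, an open file object, or an
        already-parsed mapping.

    Raises
    ------
    PanelError
        On schema violations, duplicate ids, dangling IntStd references or
        invalid dilution schemes, naming the offending field.
    """
    try:
        raw = _load_structured(config_source)
    except yaml.YAMLError as exc:  # pragma: no cover - passthrough detail
        raise PanelError(f"panel config does not parse: {exc}") from exc
    if not isinstance(raw, dict) or "analytes" not in raw:
        raise PanelError("panel config must be a mapping with an 'analytes' list")

    entries = []
    for item in raw["analytes"]:
        try:
            entries.append(Analyte.model_validate(item))
        except PanelError:
            raise
        except Exception as exc:
            raise PanelError(f"invalid analyte entry {item!r}: {exc}") from exc

    # Default IntStd pairing by ESI mode: ESI- targets normalise to the ESI-
    # IntStd, ESI+ to the ESI+ IntStd, overridable per analyte.
    by_mode = {a.esi_mode: a.id for a in entries if a.is_internal_standard}
    resolved = []
    for a in entries:
        if not a.is_internal_standard and a.internal_standard is None:
            if a.esi_mode not in by_mode:
                raise PanelError(
                    f"analyte {a.id!r}: no internal standard for mode {a.esi_mode!r}"
                )
            a = a.model_copy(update={"internal_standard": by_mode[a.esi_mode]})
        resolved.append(a)

    kwargs: dict = {"analytes": tuple(resolved)}
    for key in ("intstd_nominal", "matrices", "dilution_schemes"):
        if key in raw:
            kwargs[key] = raw[key]
    try:
        return PanelConfig.model_validate(kwargs)
    except PanelError:
        raise
    except Exception as exc:
        raise PanelError(f"invalid panel config: {exc}") from exc


def default_panel() -> PanelConfig:
    """The shipped default panel (30 quantified targets + 2 IntStds active)."""
    with resources.files("gmmquant.data").joinpath("default_panel.yaml").open() as fh:
        return load_panel(fh)


def resolve_quant_groups(panel: PanelConfig) -> dict[str, list[str]]:
    """Map reporting-entity labels to their member analyte ids.

    Co-eluting conjugated bile acids are reported as summed taurine- and
    glycine-conjugate groups; every other quantified analyte is a singleton
    group under its own id. Excluded analytes and IntStds appear in no group.
    A conjugate group with a single member degenerates to a singleton with a
    warning.
    """
    groups: dict[str, list[str]] = {}
    for a in panel.quantified:
        if a.conjugate_group != "none":
            groups.setdefault(a.conjugate_group, []).append(a.id)
    for label in list(groups):
        if len(groups[label]) < 2:
            warnings.warn(
                f"conjugate group {label!r} has a single member; "
                "treated as a singleton",
                stacklevel=2,
            )
            del groups[label]
    grouped = {m for members in groups.values() for m in members}
    for a in panel.quantified:
        if a.id not in grouped:
            groups[a.id] = [a.id]
    return groups
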
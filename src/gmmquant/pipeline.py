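"""End-to-end pipeline driver: simulate -> calibrate -> validate -> QC -> stats.

Every stage writes delimited-text outputs plus an audit log into the run
directory; all randomness derives from the single configured seed, so a rerun
with the same configuration is byte-identical. A failing stage is recorded
and its dependents skipped rather than aborting the whole run.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration, io, qc, simulate, stats, validation
from .panel import default_panel, load_panel

__all__ = ["run_pipeline", "RunResult"]


@dataclass
class RunResult:
    """Outcome of a pipeline run: output paths, stage status, key tables."""

    output_dir: Path
    stages: dict = field(default_factory=dict)
    curves: dict = field(default_factory=dict)
    quant: dict = field(default_factory=dict)
    stats_tables: dict = field(default_factory=dict)
    venn: tuple = ()

    @property
    def ok(self) -> bool:
        return all(s == "ok" for s in self.stages.values())


def _spawn_seeds(seed: int, labels: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(labels))
    return {lab: np.random.default_rng(ss) for lab, ss in zip(labels, children)}


def run_pipeline(
    config: io.RunConfig,
    instrument: simulate.InstrumentModel | None = None,
    concentration_model: simulate.ConcentrationModel | None = None,
    cohort_spec: simulate.CohortSpec | None = None,
) -> RunResult:
    """Execute the configured pipeline and write a run directory.

    The optional model arguments override the generator defaults in
    synthetic mode (e.g. a noise-free instrument for round-trip checks).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = RunResult(output_dir=outdir)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    def fail(stage: str, exc: Exception) -> None:
        result.stages[stage] = "failed"
        log(f"[{stage}] FAILED: {exc}")
        log(traceback.format_exc())

    (outdir / "config.json").write_text(
        json.dumps(config.model_dump(), indent=2, default=str)
    )

    panel = load_panel(config.panel_path) if config.panel_path else default_panel()
    summary = panel.summary()
    (outdir / "panel_summary.json").write_text(json.dumps(summary, indent=2))
    log(f"[panel] {summary}")
    result.stages["panel"] = "ok"

    seeds = _spawn_seeds(
        config.seed,
        ["cohort", "conc", "standards", "peaks", "neat", "precision", "spikes"],
    )

    # ---- inputs -----------------------------------------------------------
    peaks: dict[str, pd.DataFrame] = {}
    standards: dict[str, pd.DataFrame] = {}
    try:
        if config.input_mode == "synthetic":
            spec = cohort_spec or simulate.CohortSpec(seed=config.seed)
            subjects = simulate.simulate_cohort(spec, seed=seeds["cohort"])
            conc_model = concentration_model or simulate.default_concentration_model(
                panel
            )
            instrument = instrument or simulate.default_instrument_model(panel)
            for matrix in config.matrices:
                true_conc = simulate.sample_true_concentrations(
                    subjects, conc_model, matrix, seed=seeds["conc"]
                )
                standards[matrix] = simulate.simulate_calibration_series(
                    panel,
                    instrument,
                    matrix,
                    n_points=config.n_calibration_points,
                    replicates=config.calibration_replicates,
                    seed=seeds["standards"],
                )
                peaks[matrix] = simulate.simulate_peak_table(
                    subjects, true_conc, panel, instrument, matrix,
                    seed=seeds["peaks"],
                )
                io.write_peak_table(peaks[matrix], outdir / f"peaks_{matrix}.csv")
                io.write_peak_table(
                    standards[matrix], outdir / f"standards_{matrix}.csv"
                )
            neat_standards = simulate.simulate_calibration_series(
                panel,
                instrument,
                "neat",
                n_points=config.n_calibration_points,
                replicates=config.calibration_replicates,
                seed=seeds["neat"],
            )
            io.write_peak_table(neat_standards, outdir / "standards_neat.csv")
        else:
            subjects = io.read_cohort_table(config.cohort_path)
            instrument = None
            neat_standards = None
            for matrix in config.matrices:
                peaks[matrix] = io.read_peak_table(
                    config.peak_table_paths[matrix], panel
                )
                standards[matrix] = io.read_peak_table(
                    config.standards_paths[matrix], panel
                )
        io.write_cohort_table(subjects, outdir / "cohort.csv")
        result.stages["inputs"] = "ok"
        log(f"[inputs] {len(subjects)} subjects; matrices {list(config.matrices)}")
    except Exception as exc:
        fail("inputs", exc)
        _finish(outdir, result, log_lines)
        return result

    # ---- calibration ------------------------------------------------------
    try:
        for matrix in config.matrices:
            result.curves[matrix] = calibration.fit_all_curves(
                standards[matrix], panel, config.weighting
            )
        all_curves = {}
        for cs in result.curves.values():
            all_curves.update(cs)
        calibration.curves_to_frame(all_curves).to_csv(
            outdir / "curves.csv", index=False
        )
        result.stages["calibration"] = "ok"
        n_fail = sum(not c.ok for c in all_curves.values())
        log(f"[calibration] {len(all_curves)} curves, {n_fail} failed")
    except Exception as exc:
        fail("calibration", exc)
        _finish(outdir, result, log_lines)
        return result

    # ---- validation metrics (synthetic inputs only) -----------------------
    if config.input_mode == "synthetic":
        try:
            neat_curves = {
                a_id: c
                for (_m, a_id), c in calibration.fit_all_curves(
                    neat_standards, panel, config.weighting
                ).items()
            }
            frames = []
            for matrix in config.matrices:
                runs = simulate.simulate_precision_runs(
                    panel, instrument, matrix, seed=seeds["precision"]
                )
                spikes = simulate.simulate_spike_experiment(
                    panel, instrument, matrix, seed=seeds["spikes"]
                )
                frames.append(
                    validation.build_validation_report(
                        result.curves[matrix], neat_curves, spikes, runs, panel
                    )
                )
            report = pd.concat(frames, ignore_index=True)
            report.to_csv(outdir / "validation_report.csv", index=False)
            result.stages["validation"] = "ok"
            log(f"[validation] {len(report)} analyte x matrix rows")
        except Exception as exc:
            fail("validation", exc)

    # ---- QC cascade -------------------------------------------------------
    for matrix in config.matrices:
        stage = f"cascade_{matrix}"
        try:
            qm = qc.run_cascade(
                peaks[matrix],
                panel,
                result.curves[matrix],
                matrix,
                subjects,
                standards=standards[matrix],
                detection_threshold=config.detection_threshold,
            )
            result.quant[matrix] = qm
            qm.values.to_csv(outdir / f"quant_{matrix}.csv")
            qm.provenance.to_csv(outdir / f"provenance_{matrix}.csv")
            (outdir / f"audit_{matrix}.json").write_text(
                json.dumps(qm.audit, indent=2, default=str)
            )
            result.stages[stage] = "ok"
            log(
                f"[{stage}] retained {len(qm.entities)} entities; "
                f"provenance {qm.provenance_counts()}"
            )
        except Exception as exc:
            fail(stage, exc)

    # ---- statistics -------------------------------------------------------
    significant: dict[str, set] = {}
    for matrix in config.matrices:
        stage = f"stats_{matrix}"
        if matrix not in result.quant:
            result.stages[stage] = "skipped"
            continue
        try:
            qm = result.quant[matrix]
            res = stats.adjusted_group_test(
                qm,
                log_transform=config.log_transform,
                adjust_method=config.adjust_method,
            )
            res["stars"] = res["p_raw"].map(
                lambda p: stats.significance_label(p) if np.isfinite(p) else ""
            )
            res.to_csv(outdir / f"stats_{matrix}.csv", index=False)
            result.stats_tables[matrix] = res
            significant[matrix] = set(
                res.loc[res["p_adjusted"] < config.alpha, "entity"]
            )
            comp = stats.composition_profile(qm)
            comp.to_csv(outdir / f"composition_{matrix}.csv")
            pca = stats.pca_scores(qm)
            pca.scores.to_csv(outdir / f"pca_scores_{matrix}.csv")
            result.stages[stage] = "ok"
            log(
                f"[{stage}] {len(significant[matrix])} significant entities "
                f"at adjusted p < {config.alpha}"
            )
        except Exception as exc:
            fail(stage, exc)

    if {"plasma", "feces"} <= set(significant):
        fecal_only, shared, plasma_only = stats.venn_partition(
            significant["feces"], significant["plasma"]
        )
        result.venn = (fecal_only, shared, plasma_only)
        (outdir / "venn.json").write_text(
            json.dumps(
                {
                    "fecal_only": sorted(fecal_only),
                    "shared": sorted(shared),
                    "plasma_only": sorted(plasma_only),
                    "counts": [len(fecal_only), len(shared), len(plasma_only)],
                },
                indent=2,
            )
        )
        log(
            f"[venn] fecal-only {len(fecal_only)}, shared {len(shared)}, "
            f"plasma-only {len(plasma_only)}"
        )

    # cohort characteristics summary (median +/- MAD age, sex chi-square)
    try:
        tab = pd.crosstab(subjects["sex"], subjects["group"])
        chi2 = p_sex = float("nan")
        if tab.shape == (2, 2) and (tab.to_numpy() > 0).all():
            chi2, p_sex = stats.chi_square_2x2(tab.to_numpy())
        rows = []
        for g, grp in subjects.groupby("group"):
            med, mad = stats.median_mad_summary(grp["age"])
            rows.append(
                {
                    "group": g,
                    "n": len(grp),
                    "age_median": med,
                    "age_mad": mad,
                    "n_female": int((grp["sex"] == "F").sum()),
                }
            )
        cohort_summary = pd.DataFrame(rows)
        cohort_summary["sex_chi2"] = chi2
        cohort_summary["sex_p"] = p_sex
        cohort_summary.to_csv(outdir / "cohort_summary.csv", index=False)
        result.stages["cohort_summary"] = "ok"
    except Exception as exc:
        fail("cohort_summary", exc)

    _finish(outdir, result, log_lines)
    return result


def _finish(outdir: Path, result: RunResult, log_lines: list[str]) -> None:
    log_lines.append(f"[done] stages: {result.stages}")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
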
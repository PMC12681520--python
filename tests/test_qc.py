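"""QC cascade rules: detection filter, imputation, IntStd gate, collapsing."""

import numpy as np
import pandas as pd
import pytest

from gmmquant.calibration import fit_all_curves
from gmmquant.qc import (
    CascadeError,
    collapse_conjugates,
    detection_rate_filter,
    gate_internal_standard,
    impute_group_median_flagged,
    impute_group_minimum,
    intstd_reference_from_standards,
    run_cascade,
)
from gmmquant.simulate import (
    sample_true_concentrations,
    simulate_calibration_series,
    simulate_peak_table,
)

M = "measured"
C = "censored"


class TestDetectionRateFilter:
    def test_below_threshold_in_one_group_drops(self, make_qm):
        # 7/10 detected in HC (70 % < 80 %), 10/10 in PD -> dropped
        hc = [1.0] * 7 + [np.nan] * 3
        qm = make_qm({"X": hc + [1.0] * 10}, ["HC"] * 10 + ["PD"] * 10)
        out = detection_rate_filter(qm)
        assert out.entities == []
        assert out.audit[-1]["dropped_entities"] == ["X"]

    def test_exactly_80pct_retained(self, make_qm):
        grp = [1.0] * 8 + [np.nan] * 2
        qm = make_qm({"X": grp + grp}, ["HC"] * 10 + ["PD"] * 10)
        assert detection_rate_filter(qm).entities == ["X"]

    def test_fully_detected_retained(self, make_qm):
        qm = make_qm({"X": [1.0] * 8}, ["HC"] * 4 + ["PD"] * 4)
        assert detection_rate_filter(qm).entities == ["X"]


class TestImputeGroupMinimum:
    def test_missing_gets_group_minimum(self, make_qm):
        qm = make_qm({"X": [np.nan, 2, 5, 1, 1, 1]}, ["HC"] * 3 + ["PD"] * 3)
        out = impute_group_minimum(qm)
        assert out.values["X"].tolist() == [2, 2, 5, 1, 1, 1]
        assert out.provenance["X"].tolist()[0] == "imputed_min"

    def test_no_missing_is_identity(self, make_qm):
        qm = make_qm({"X": [1.0, 2.0, 3.0, 4.0]}, ["HC"] * 2 + ["PD"] * 2)
        out = impute_group_minimum(qm)
        pd.testing.assert_frame_equal(out.values, qm.values)
        assert (out.provenance == "measured").all().all()

    def test_groups_imputed_independently(self, make_qm):
        qm = make_qm(
            {"X": [np.nan, 2, 5, 1, np.nan, 4]}, ["HC"] * 3 + ["PD"] * 3
        )
        out = impute_group_minimum(qm)
        # brute-force: HC min of {2,5}=2; PD min of {1,4}=1
        assert out.values["X"].tolist() == [2, 2, 5, 1, 1, 4]

    def test_no_donor_values_is_error(self, make_qm):
        qm = make_qm({"X": [np.nan, np.nan, 1.0, 2.0]}, ["HC"] * 2 + ["PD"] * 2)
        with pytest.raises(CascadeError, match="donor"):
            impute_group_minimum(qm)


def _gate_peaks(intstd_areas, mode_analyte="IS"):
    rows = []
    for sid, area in intstd_areas.items():
        rows.append(
            {
                "sample_id": sid,
                "analyte_id": mode_analyte,
                "matrix": "plasma",
                "dilution_factor": 1.0,
                "analyte_area": 1.0,
                "intstd_area": area,
                "batch": "b1",
                "day": "d1",
                "role": "cohort",
                "nominal_conc": np.nan,
            }
        )
    return pd.DataFrame(rows)


class TestIntStdGate:
    def test_recovery_thresholds_are_strict(self, panel):
        # reference area 10 => recovery % = area x 10
        peaks = _gate_peaks({"s79": 7.9, "s80": 8.0, "s120": 12.0, "s121": 12.1})
        flagged = gate_internal_standard(peaks, panel, {"negative": 10.0})
        assert flagged["negative"] == {"s79": "low", "s121": "high"}

    def test_missing_intstd_flagged(self, panel):
        peaks = _gate_peaks({"s1": np.nan})
        flagged = gate_internal_standard(peaks, panel, {"negative": 10.0})
        assert flagged["negative"] == {"s1": "missing_intstd"}

    def test_simulated_suppression_is_caught(
        self, panel, nf_instrument, conc_model, small_cohort
    ):
        inst = nf_instrument.model_copy(
            update={"suppression_prob": 1.0, "suppression_magnitude": 0.5}
        )
        tc = sample_true_concentrations(small_cohort, conc_model, "plasma", seed=2)
        std = simulate_calibration_series(panel, nf_instrument, "plasma", seed=2)
        peaks = simulate_peak_table(small_cohort, tc, panel, inst, "plasma", seed=2)
        ref = intstd_reference_from_standards(std, panel)
        flagged = gate_internal_standard(peaks, panel, ref)
        for mode in ("positive", "negative"):
            assert set(flagged[mode]) == set(small_cohort["subject_id"])
            assert set(flagged[mode].values()) == {"low"}


class TestImputeGroupMedianFlagged:
    def test_flagged_sample_gets_group_median(self, make_qm):
        qm = make_qm({"X": [9.0, 1.0, 3.0, 5.0]}, ["PD"] * 4)
        flagged = {"negative": {"S01": "low"}, "positive": {}}
        out = impute_group_median_flagged(qm, flagged, {"X": "negative"})
        assert out.values["X"].tolist() == [3.0, 1.0, 3.0, 5.0]
        assert out.provenance.at["S01", "X"] == "imputed_median"

    def test_no_flags_is_identity(self, make_qm):
        qm = make_qm({"X": [1.0, 2.0, 3.0, 4.0]}, ["HC"] * 2 + ["PD"] * 2)
        out = impute_group_median_flagged(
            qm, {"negative": {}, "positive": {}}, {"X": "negative"}
        )
        pd.testing.assert_frame_equal(out.values, qm.values)

    def test_two_flagged_share_donor_median(self, make_qm):
        qm = make_qm({"X": [10.0, 20.0, 2.0, 4.0, 6.0]}, ["HC"] * 5)
        flagged = {"negative": {"S01": "low", "S02": "high"}, "positive": {}}
        out = impute_group_median_flagged(qm, flagged, {"X": "negative"})
        # brute-force: median of donors {2,4,6} = 4 for both
        assert out.values["X"].tolist() == [4.0, 4.0, 2.0, 4.0, 6.0]

    def test_all_flagged_group_is_error(self, make_qm):
        qm = make_qm({"X": [1.0, 2.0]}, ["PD", "PD"])
        flagged = {"negative": {"S01": "low", "S02": "low"}, "positive": {}}
        with pytest.raises(CascadeError, match="donor"):
            impute_group_median_flagged(qm, flagged, {"X": "negative"})

    def test_flagged_in_other_mode_untouched(self, make_qm):
        qm = make_qm({"X": [9.0, 1.0, 3.0]}, ["PD"] * 3)
        flagged = {"negative": {}, "positive": {"S01": "low"}}
        out = impute_group_median_flagged(qm, flagged, {"X": "negative"})
        assert out.values["X"].tolist() == [9.0, 1.0, 3.0]


class TestCollapseConjugates:
    GROUPS = {"taurine_conjugates": ["TCDCA", "TDCA", "TUDCA"], "HA": ["HA"]}

    def test_members_sum(self, make_qm):
        qm = make_qm(
            {"TCDCA": [1.0], "TDCA": [2.0], "TUDCA": [3.0], "HA": [7.0]}, ["HC"]
        )
        out = collapse_conjugates(qm, self.GROUPS)
        assert out.values.at["S01", "taurine_conjugates"] == 6.0
        assert out.provenance.at["S01", "taurine_conjugates"] == "measured"

    def test_singletons_identity(self, make_qm):
        qm = make_qm({"HA": [7.0, 8.0]}, ["HC", "PD"])
        out = collapse_conjugates(qm, {"HA": ["HA"]})
        assert out.values["HA"].tolist() == [7.0, 8.0]

    def test_weakest_member_provenance_wins(self, make_qm):
        qm = make_qm(
            {"TCDCA": [1.0], "TDCA": [np.nan], "TUDCA": [3.0], "HA": [7.0]},
            ["HC"],
            provenance={
                "TCDCA": [M], "TDCA": [C], "TUDCA": [M], "HA": [M],
            },
        )
        out = collapse_conjugates(qm, self.GROUPS)
        assert out.provenance.at["S01", "taurine_conjugates"] == C
        assert np.isnan(out.values.at["S01", "taurine_conjugates"])

    def test_partial_membership_warns(self, make_qm):
        qm = make_qm({"TCDCA": [1.0], "TDCA": [2.0]}, ["HC"])
        with pytest.warns(UserWarning, match="missing from the matrix"):
            out = collapse_conjugates(
                qm, {"taurine_conjugates": ["TCDCA", "TDCA", "TUDCA"]}
            )
        assert out.values.at["S01", "taurine_conjugates"] == 3.0


@pytest.fixture(scope="module")
def cascade_inputs(panel, instrument, conc_model, full_cohort):
    tc = sample_true_concentrations(full_cohort, conc_model, "feces", seed=31)
    std = simulate_calibration_series(panel, instrument, "feces", seed=31)
    curves = fit_all_curves(std, panel)
    peaks = simulate_peak_table(
        full_cohort, tc, panel, instrument, "feces", seed=31
    )
    return peaks, curves, std, full_cohort


class TestFullCascade:
    def test_no_missing_cells_after_cascade(self, panel, cascade_inputs):
        peaks, curves, std, cohort = cascade_inputs
        qm = run_cascade(peaks, panel, curves, "feces", cohort, standards=std)
        assert qm.is_complete()

    def test_retained_entities_match_generator_detectability(
        self, panel, conc_model, cascade_inputs
    ):
        """Brute-force recount: entities whose members are all generated as
        detectable in feces are exactly the retained ones."""
        from gmmquant.panel import resolve_quant_groups

        peaks, curves, std, cohort = cascade_inputs
        qm = run_cascade(peaks, panel, curves, "feces", cohort, standards=std)
        laws = conc_model.for_matrix("feces")
        expected = {
            label
            for label, members in resolve_quant_groups(panel).items()
            if all(laws[m].detect_prob >= 0.8 for m in members)
        }
        assert set(qm.entities) == expected

    def test_cascade_is_idempotent(self, panel, cascade_inputs):
        from gmmquant.panel import resolve_quant_groups
        from gmmquant.qc import intstd_reference_from_standards

        peaks, curves, std, cohort = cascade_inputs
        qm = run_cascade(peaks, panel, curves, "feces", cohort, standards=std)
        groups = resolve_quant_groups(panel)
        mode_of = {a.id: a.esi_mode for a in panel.analytes}
        entity_modes = {lab: mode_of[mm[0]] for lab, mm in groups.items()}
        flagged = gate_internal_standard(
            peaks, panel, intstd_reference_from_standards(std, panel)
        )
        again = collapse_conjugates(qm, groups)
        again = detection_rate_filter(again)
        again = impute_group_minimum(again)
        again = impute_group_median_flagged(again, flagged, entity_modes)
        pd.testing.assert_frame_equal(
            again.values[qm.entities], qm.values
        )
        pd.testing.assert_frame_equal(
            again.provenance[qm.entities], qm.provenance
        )

    def test_audit_counts_reconcile_with_provenance(self, panel, cascade_inputs):
        peaks, curves, std, cohort = cascade_inputs
        qm = run_cascade(peaks, panel, curves, "feces", cohort, standards=std)
        counts = qm.provenance_counts()
        audit = {e["rule"]: e for e in qm.audit}
        median_entry = audit["impute_group_median_flagged"]
        assert counts.get("imputed_median", 0) == median_entry["cells_imputed"]
        assert (
            counts.get("imputed_min", 0)
            == audit["impute_group_minimum"]["cells_imputed"]
            - median_entry["overwrote_imputed_min"]
        )
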
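"""Cohort statistics: adjusted tests, nonparametrics, adjustments, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmmquant.stats import (
    adjusted_group_test,
    benjamini_hochberg_adjust,
    chi_square_2x2,
    composition_profile,
    holm_sidak_adjust,
    mannwhitney_exact,
    median_mad_summary,
    pca_scores,
    significance_label,
    spearman_bh,
    subgroup_mannwhitney,
    venn_partition,
)
from oracles import bh_brute, holm_sidak_brute, mannwhitney_exact_brute

p_vectors = st.lists(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
    min_size=1,
    max_size=10,
)


class TestAdjustedGroupTest:
    def _qm_with_meta(self, make_qm, values, groups, ages=None, sexes=None):
        qm = make_qm(values, groups)
        meta = qm.sample_meta.copy()
        n = len(groups)
        meta["age"] = ages if ages is not None else np.linspace(20, 60, n)
        meta["sex"] = sexes if sexes is not None else ["F", "M"] * (n // 2)
        return type(qm)(qm.values, qm.provenance, meta, qm.matrix)

    def test_exact_group_offset_recovered(self, make_qm):
        groups = ["HC"] * 4 + ["PD"] * 4
        # log response = 2 x group indicator exactly; covariates balanced
        vals = [1.0] * 4 + [float(np.exp(2.0))] * 4
        qm = self._qm_with_meta(
            make_qm, {"X": vals}, groups,
            ages=[30, 40, 50, 60] * 2, sexes=["F", "M"] * 4,
        )
        res = adjusted_group_test(qm)
        assert res.at[0, "effect"] == pytest.approx(2.0)
        assert res.at[0, "p_raw"] < 1e-10

    def test_constant_entity_flagged_not_dropped(self, make_qm):
        qm = self._qm_with_meta(
            make_qm,
            {"X": [1.0] * 8, "Y": [1, 2, 3, 4, 5, 6, 7, 8]},
            ["HC"] * 4 + ["PD"] * 4,
        )
        res = adjusted_group_test(qm).set_index("entity")
        assert res.at["X", "flag"] == "constant"
        assert np.isnan(res.at["X", "p_raw"])
        assert np.isfinite(res.at["Y", "p_raw"])

    def test_incomplete_matrix_rejected(self, make_qm):
        qm = self._qm_with_meta(
            make_qm, {"X": [1, np.nan, 3, 4]}, ["HC", "HC", "PD", "PD"]
        )
        with pytest.raises(ValueError, match="missing"):
            adjusted_group_test(qm)

    def test_null_permutation_type_I_error(self, make_qm, full_cohort):
        """Empirical alpha under a permuted-null within the binomial band."""
        rng = np.random.default_rng(2024)
        n = len(full_cohort)
        reps = 400
        vals = {f"e{i}": np.exp(rng.standard_normal(n)) for i in range(reps)}
        qm = make_qm(vals, list(full_cohort["group"]))
        meta = qm.sample_meta.copy()
        meta["age"] = full_cohort["age"].to_numpy()
        meta["sex"] = full_cohort["sex"].to_numpy()
        qm = type(qm)(qm.values, qm.provenance, meta, qm.matrix)
        res = adjusted_group_test(qm)
        alpha = (res["p_raw"] < 0.05).mean()
        band = 1.96 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(alpha - 0.05) < band + 1e-12


class TestMannWhitney:
    def test_exact_small_sample(self):
        u, p = mannwhitney_exact([1, 2, 3], [4, 5, 6])
        assert (u, p) == (0.0, pytest.approx(0.1))

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a = rng.permutation(20)[:4].tolist()
            b = rng.permutation(np.arange(100, 120))[:5].tolist()
            u, p = mannwhitney_exact(a, b)
            u_o, p_o = mannwhitney_exact_brute(a, b)
            assert u == u_o
            assert p == pytest.approx(p_o)

    def test_identical_groups_p_one(self):
        _u, p = mannwhitney_exact([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mannwhitney_exact([], [1])

    def test_family_holm_sidak_worked_example(self):
        fam = subgroup_mannwhitney(
            [([1, 2, 3], [4, 5, 6]), ([1, 2], [3, 4])], labels=["a", "b"]
        )
        # raw p: 0.1 (exact) and 1/3 (exact, C(4,2)=6, U extremes 2/6)
        assert fam["p_raw"].tolist() == pytest.approx([0.1, 1 / 3])
        expected = holm_sidak_brute(np.array([0.1, 1 / 3]))
        assert fam["p_holm_sidak"].to_numpy() == pytest.approx(expected)


class TestMultipleTesting:
    def test_holm_sidak_worked_example(self):
        assert holm_sidak_adjust([0.01, 0.04]) == pytest.approx([0.0199, 0.04])

    def test_bh_worked_example(self):
        assert benjamini_hochberg_adjust([0.01, 0.02, 0.06]) == pytest.approx(
            [0.03, 0.03, 0.06]
        )

    @settings(derandomize=True, max_examples=200)
    @given(p=p_vectors)
    def test_both_match_bruteforce_definitions(self, p):
        p = np.asarray(p)
        assert holm_sidak_adjust(p) == pytest.approx(holm_sidak_brute(p))
        assert benjamini_hochberg_adjust(p) == pytest.approx(bh_brute(p))

    @settings(derandomize=True, max_examples=100)
    @given(p=p_vectors)
    def test_adjusted_at_least_raw_and_monotone(self, p):
        p = np.asarray(p)
        for adj in (holm_sidak_adjust(p), benjamini_hochberg_adjust(p)):
            assert (adj >= p - 1e-12).all()
            order = np.argsort(p, kind="stable")
            assert (np.diff(adj[order]) >= -1e-12).all()


class TestChiSquare:
    def test_sex_table_reproduces_printed_p(self):
        stat, p = chi_square_2x2([[32, 7], [25, 21]])
        assert f"{p:.3g}" == "0.00677"

    def test_proportional_table_null(self):
        stat, p = chi_square_2x2([[10, 20], [5, 10]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_perfect_association(self):
        stat, _p = chi_square_2x2([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 0], [5, 10]])


class TestSpearman:
    def test_monotone_pair_rho_one(self):
        ent = pd.DataFrame({"X": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
        var = pd.DataFrame({"v": [10.0, 20.0, 30.0, 40.0]}, index=list("abcd"))
        res = spearman_bh(ent, var)
        assert res.at[0, "rho"] == pytest.approx(1.0)

    def test_pairwise_deletion_and_min_pairs(self):
        ent = pd.DataFrame({"X": [1.0, 2.0, np.nan, 4.0]}, index=list("abcd"))
        var = pd.DataFrame(
            {"v": [1.0, 2.0, 3.0, 4.0], "w": [1.0, np.nan, np.nan, 2.0]},
            index=list("abcd"),
        )
        res = spearman_bh(ent, var).set_index("variable")
        assert res.at["v", "n"] == 3
        assert np.isnan(res.at["w", "rho"])  # only 2 paired points: skipped

    def test_independent_pairs_fdr_controlled(self):
        rng = np.random.default_rng(11)
        ent = pd.DataFrame(
            rng.standard_normal((40, 25)),
            columns=[f"e{i}" for i in range(25)],
        )
        var = pd.DataFrame(rng.standard_normal((40, 4)), columns=list("wxyz"))
        res = spearman_bh(ent, var)
        assert (res["significant"]).mean() <= 0.05


class TestCompositionProfile:
    def test_two_entities(self, make_qm):
        qm = make_qm({"A": [94.0, 94.0], "B": [6.0, 6.0]}, ["HC", "PD"])
        prof = composition_profile(qm)
        assert prof.loc["HC", "A"] == pytest.approx(94.0)
        assert prof.loc["HC", "B"] == pytest.approx(6.0)

    def test_single_entity_is_100(self, make_qm):
        qm = make_qm({"A": [3.0, 5.0]}, ["HC", "PD"])
        assert (composition_profile(qm) == 100.0).all().all()

    def test_rows_sum_to_100(self, make_qm):
        rng = np.random.default_rng(3)
        qm = make_qm(
            {f"e{i}": rng.lognormal(size=6) for i in range(5)},
            ["HC"] * 3 + ["PD"] * 3,
        )
        assert composition_profile(qm).sum(axis=1).to_numpy() == pytest.approx(
            [100.0, 100.0]
        )


class TestPca:
    def test_one_dimensional_data(self, make_qm):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        qm = make_qm(
            {"A": np.exp(t), "B": np.exp(2 * t)}, ["HC", "HC", "PD", "PD"]
        )
        res = pca_scores(qm)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_explained_variance_sums_to_one_and_scores_orthogonal(self, make_qm):
        rng = np.random.default_rng(8)
        qm = make_qm(
            {f"e{i}": rng.lognormal(size=12) for i in range(4)},
            ["HC"] * 6 + ["PD"] * 6,
        )
        res = pca_scores(qm)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)
        gram = res.scores.T @ res.scores
        off = gram.to_numpy() - np.diag(np.diag(gram))
        assert np.allclose(off, 0, atol=1e-8)

    def test_group_separation_with_and_without_effect(self, panel):
        """Strong simulated group effects separate centroids on PC1; null
        effects do not (mirrors the plasma-vs-feces contrast)."""
        from gmmquant import calibration, qc, simulate

        for null, expect_sep in ((False, True), (True, False)):
            conc = simulate.default_concentration_model(panel)
            if null:
                levels = {
                    m: {
                        a: lv.model_copy(update={"fold_change": 1.0})
                        for a, lv in d.items()
                    }
                    for m, d in conc.levels.items()
                }
                conc = simulate.ConcentrationModel(levels=levels)
            inst = simulate.default_instrument_model(panel)
            cohort = simulate.simulate_cohort(simulate.CohortSpec(seed=17))
            tc = simulate.sample_true_concentrations(cohort, conc, "plasma", 18)
            std = simulate.simulate_calibration_series(panel, inst, "plasma", seed=18)
            curves = calibration.fit_all_curves(std, panel)
            peaks = simulate.simulate_peak_table(
                cohort, tc, panel, inst, "plasma", seed=18
            )
            qm = qc.run_cascade(peaks, panel, curves, "plasma", cohort, standards=std)
            res = pca_scores(qm)
            pc1 = res.scores["PC1"]
            grp = qm.groups()
            sep = abs(pc1[grp == "PD"].mean() - pc1[grp == "HC"].mean())
            spread = max(pc1[grp == "PD"].std(), pc1[grp == "HC"].std())
            assert (sep > spread) == expect_sep

    def test_zero_variance_column_dropped_with_warning(self, make_qm):
        qm = make_qm(
            {"A": [1.0, 1.0, 1.0, 1.0], "B": [1, 2, 3, 4], "C": [4, 3, 2, 1]},
            ["HC", "HC", "PD", "PD"],
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pca_scores(qm)
        assert res.dropped_columns == ("A",)


class TestMedianMad:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1, 2, 3], (2.0, 1.0)),
            ([7, 7, 7, 7], (7.0, 0.0)),
            ([65, 80, 50, 65, 95, 35], (65.0, 15.0)),
        ],
    )
    def test_worked_examples(self, values, expected):
        assert median_mad_summary(values) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_mad_summary([])


class TestVenn:
    def test_worked_example(self):
        assert venn_partition({"a", "b", "c"}, {"c", "d"}) == (
            {"a", "b"},
            {"c"},
            {"d"},
        )

    def test_disjoint_and_equal(self):
        assert venn_partition({"a"}, {"b"})[1] == set()
        only_f, shared, only_p = venn_partition({"a", "b"}, {"a", "b"})
        assert (only_f, shared, only_p) == (set(), {"a", "b"}, set())

    @settings(derandomize=True, max_examples=50)
    @given(
        f=st.sets(st.sampled_from("abcdefgh")),
        p=st.sets(st.sampled_from("abcdefgh")),
    )
    def test_partition_property(self, f, p):
        only_f, shared, only_p = venn_partition(f, p)
        assert only_f | shared == f
        assert only_p | shared == p
        assert not (only_f & only_p)


def test_significance_labels():
    assert significance_label(0.2) == "ns"
    assert significance_label(0.03) == "*"
    assert significance_label(0.004) == "**"
    assert significance_label(5e-5) == "****"
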
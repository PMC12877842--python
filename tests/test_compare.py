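"""Stratified z-tests, sensitivity summaries, concordance classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rplphewas import compare


def make_results(phecodes, ors, p_adjs, converged=None, n_rpl_with=50,
                 n_control_with=50):
    n = len(phecodes)
    ors = np.asarray(ors, dtype=float)
    return pd.DataFrame(
        {
            "phecode": phecodes,
            "beta": np.log(ors),
            "se": np.full(n, 0.1),
            "or_value": ors,
            "p": p_adjs,
            "p_adj": p_adjs,
            "converged": converged if converged is not None else [True] * n,
            "n_rpl_with": np.full(n, n_rpl_with),
            "n_control_with": np.full(n, n_control_with),
            "n_rpl": np.full(n, 500),
            "n_control": np.full(n, 1500),
        }
    )


class TestCoefficientZTests:
    def test_closed_form_example(self):
        ry = make_results(["x"], [np.exp(0.7)], [0.01])
        ro = make_results(["x"], [np.exp(0.3)], [0.01])
        out = compare.coefficient_z_tests(ry, ro)
        assert out.loc[0, "z"] == pytest.approx(0.4 / np.sqrt(0.02), rel=1e-9)
        assert out.loc[0, "p"] == pytest.approx(2 * stats.norm.sf(2.8284), rel=1e-3)
        assert out.loc[0, "p"] == pytest.approx(0.00468, abs=5e-5)
        assert out.loc[0, "higher_stratum"] == "under35"

    def test_equal_betas_give_null(self):
        ry = make_results(["x"], [2.0], [0.01])
        ro = make_results(["x"], [2.0], [0.01])
        out = compare.coefficient_z_tests(ry, ro)
        assert out.loc[0, "z"] == 0
        assert out.loc[0, "p"] == pytest.approx(1.0)
        assert out.loc[0, "higher_stratum"] == "tie"

    def test_nonconverged_excluded(self):
        ry = make_results(["x", "y"], [2.0, 3.0], [0.01, 0.01],
                          converged=[True, False])
        ro = make_results(["x", "y"], [2.0, 3.0], [0.01, 0.01])
        out = compare.coefficient_z_tests(ry, ro)
        assert list(out["phecode"]) == ["x"]


class TestStratifyAndTest:
    def test_runs_on_generated_center(self, small_matrix):
        ry, ro, comparison = compare.stratify_and_test(small_matrix)
        assert set(ry["phecode"]) == set(ro["phecode"])
        assert len(comparison) <= len(ry)
        assert comparison["p"].between(0, 1).all()

    def test_stratum_without_cases_errors(self, small_matrix):
        with pytest.raises(ValueError, match="lacks"):
            compare.stratify_and_test(small_matrix, cutoff=80.0)


class TestUtilizationSensitivity:
    def test_pct_change_arithmetic(self):
        assert compare.pct_change(2.0, 1.74) == pytest.approx(-13.0)

    def test_summary_on_generated_center(self, small_matrix):
        sens = compare.utilization_sensitivity(small_matrix)
        assert len(sens.per_diagnosis) == len(small_matrix.phecodes)
        # no utilization link in this generator run: median change near zero
        assert abs(sens.median_pct_change) < 5.0
        assert sens.union_significant <= set(small_matrix.phecodes)


class TestCompareCenters:
    def _fixture_tables(self):
        a = make_results(
            ["p1", "p2", "p3", "p4", "p5"],
            [2.0, 0.5, 2.0, 2.0, 1.5],
            [0.001, 0.001, 0.001, 0.5, 0.5],
        )
        b = make_results(
            ["p1", "p2", "p3", "p4", "p5"],
            [3.0, 0.4, 0.5, 2.0, 1.2],
            [0.001, 0.001, 0.001, 0.001, 0.5],
        )
        return a, b

    def test_class_definitions_exact(self):
        a, b = self._fixture_tables()
        out = compare.compare_centers(a, b).set_index("phecode")
        assert out.loc["p1", "class"] == "validated_positive"
        assert out.loc["p2", "class"] == "validated_negative"
        assert out.loc["p3", "class"] == "discordant"
        assert out.loc["p4", "class"] == "single_center_only"
        assert out.loc["p5", "class"] == "neither"

    def test_classes_partition_shared_candidates(self):
        a, b = self._fixture_tables()
        out = compare.compare_centers(a, b)
        assert out["class"].isin(compare.CONCORDANCE_CLASSES).all()
        assert len(out) == 5

    def test_rank_identical_fixtures_give_spearman_one(self):
        a = make_results(["p1", "p2", "p3"], [1.5, 2.0, 3.0], [0.001] * 3)
        b = make_results(["p1", "p2", "p3"], [1.2, 2.5, 9.0], [0.001] * 3)
        out = compare.compare_centers(a, b)
        assert out.attrs["spearman_r"] == pytest.approx(1.0)

    def test_spearman_invariant_to_log_transform(self):
        a = make_results(["p1", "p2", "p3", "p4"], [1.5, 2.0, 3.0, 0.5], [0.001] * 4)
        b = make_results(["p1", "p2", "p3", "p4"], [1.2, 2.5, 9.0, 0.4], [0.001] * 4)
        r_or = stats.spearmanr(a["or_value"], b["or_value"]).statistic
        r_log = stats.spearmanr(np.log(a["or_value"]), np.log(b["or_value"])).statistic
        assert r_or == pytest.approx(r_log)

    def test_plot_filter_rule(self):
        a = make_results(["p1", "p2"], [2.0, 2.0], [0.001] * 2,
                         n_rpl_with=5, n_control_with=12)
        b = make_results(["p1", "p2"], [2.0, 2.0], [0.001] * 2,
                         n_rpl_with=5, n_control_with=5)
        out = compare.compare_centers(a, b)
        # >= 10 in either group required at BOTH centers; center B fails
        assert not out["plot_filter"].any()

    def test_empty_shared_set_errors(self):
        a = make_results(["p1"], [2.0], [0.001])
        b = make_results(["p2"], [2.0], [0.001])
        with pytest.raises(ValueError, match="shared"):
            compare.compare_centers(a, b)


class TestCompareWithin:
    def test_variant_copy_reproduces_main(self):
        main = make_results(["p1", "p2", "p3"], [2.0, 0.5, 1.1],
                            [0.001, 0.001, 0.9])
        out = compare.compare_within(main, main.copy())
        assert set(out["phecode"]) == {"p1", "p2"}
        assert out.attrs["spearman_r"] == pytest.approx(1.0)

    def test_disjoint_significant_sets_concatenate(self):
        main = make_results(["p1", "p2"], [2.0, 1.1], [0.001, 0.9])
        variant = make_results(["p1", "p2"], [2.0, 1.3], [0.9, 0.001])
        out = compare.compare_within(main, variant)
        assert set(out["phecode"]) == {"p1", "p2"}

    def test_hand_built_five_diagnosis_fixture(self):
        main = make_results(
            ["a", "b", "c", "d", "e"], [2.0, 0.5, 1.5, 1.0, 3.0],
            [0.001, 0.01, 0.2, 0.9, 0.04],
        )
        variant = make_results(
            ["a", "b", "c", "d", "e"], [1.8, 0.6, 1.4, 1.0, 2.5],
            [0.002, 0.3, 0.01, 0.9, 0.2],
        )
        out = compare.compare_within(main, variant)
        # union of significant sets: main {a,b,e}, variant {a,c}
        assert set(out["phecode"]) == {"a", "b", "c", "e"}
        assert out.attrs["spearman_r"] == pytest.approx(1.0)  # same ranking
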
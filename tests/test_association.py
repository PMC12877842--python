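"""Crude/adjusted models, BH adjustment, redaction, degenerate designs."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from rplphewas import association as assoc
from rplphewas import synth
from rplphewas.association import ModelSpec


def brute_force_bh(p):
    """Textbook step-up: adj_(i) = min_{j>=i} min(1, m * p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, p[order] * m / np.arange(1, m + 1))
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestCrudeOr:
    def test_closed_form(self):
        or_v, ci, p, converged = assoc.crude_or(30, 70, 10, 90)
        assert or_v == pytest.approx((30 * 90) / (70 * 10), rel=1e-12)
        assert converged
        assert ci[0] < or_v < ci[1]
        assert p < 0.01

    def test_symmetric_table_is_null(self):
        or_v, _, p, _ = assoc.crude_or(50, 50, 50, 50)
        assert or_v == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_zero_cell_flagged(self):
        or_v, ci, p, converged = assoc.crude_or(0, 100, 10, 90)
        assert not converged
        assert np.isfinite(or_v) and or_v < 1  # continuity-corrected estimate

    def test_zero_margin_undefined(self):
        or_v, ci, p, converged = assoc.crude_or(0, 0, 10, 90)
        assert not converged and np.isnan(or_v)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            assoc.crude_or(-1, 1, 1, 1)


class TestBhAdjust:
    def test_hand_example(self):
        out = assoc.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert assoc.bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(assoc.bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_nan_passthrough(self):
        out = assoc.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], brute_force_bh([0.01, 0.04]))

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_output_bounded_and_not_below_input(self, p):
        out = assoc.bh_adjust(p)
        assert (out >= np.asarray(p) - 1e-12).all()
        assert (out <= 1.0 + 1e-12).all()


def simulate_unconfounded(rng, n=4000, prevalence=0.2, or_true=2.5):
    """Covariates independent of exposure and outcome."""
    y = (rng.random(n) < 0.3).astype(float)
    logit0 = np.log(prevalence / (1 - prevalence))
    eta = logit0 + y * np.log(or_true)
    x = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    age = rng.uniform(18, 44, n)
    race = rng.choice(["W", "A", "B"], n)
    eth = rng.choice(["H", "N"], n)
    return y, x, age, race, eth


class TestFitAdjusted:
    def test_matches_crude_without_confounding(self, rng):
        y, x, age, race, eth = simulate_unconfounded(rng)
        res = assoc.fit_adjusted(y, x, age, race, eth)
        n11 = int(x[y == 1].sum()); n10 = int(x[y == 0].sum())
        n01 = int((y == 1).sum()) - n11; n00 = int((y == 0).sum()) - n10
        crude, _, _, _ = assoc.crude_or(n11, n10, n01, n00)
        assert res.converged
        assert res.or_value == pytest.approx(crude, rel=0.02)

    def test_linear_age_equals_plain_logistic(self, rng):
        y, x, age, race, eth = simulate_unconfounded(rng, n=2000)
        spec = ModelSpec(age_linear=True)
        res = assoc.fit_adjusted(y, x, age, race, eth, spec=spec)
        X0, _ = assoc.build_design(age, race, eth, spec=spec)
        X = np.column_stack([X0, x])
        oracle = sm.Logit(y, X).fit(disp=0)
        assert res.beta == pytest.approx(oracle.params[-1], abs=1e-6)
        assert res.se == pytest.approx(oracle.bse[-1], abs=1e-6)

    def test_null_planted_or_estimates_near_one(self, rng):
        y, x, age, race, eth = simulate_unconfounded(rng, n=10000, or_true=1.0)
        res = assoc.fit_adjusted(y, x, age, race, eth)
        assert abs(res.beta) < 3 * res.se

    def test_penalized_smooth_close_to_unpenalized(self, rng):
        y, x, age, race, eth = simulate_unconfounded(rng, n=3000)
        res_plain = assoc.fit_adjusted(y, x, age, race, eth)
        res_pen = assoc.fit_adjusted(
            y, x, age, race, eth, spec=ModelSpec(penalized=True, penalty_alpha=1.0)
        )
        assert res_pen.converged
        assert res_pen.or_value == pytest.approx(res_plain.or_value, rel=0.05)

    def test_perfect_separation_flagged_with_direction(self, rng):
        n = 400
        y = np.repeat([0.0, 1.0], n // 2)
        x = y.copy()  # exposure perfectly predicts case status
        age = rng.uniform(18, 44, n)
        race = rng.choice(["W", "A"], n)
        eth = rng.choice(["H", "N"], n)
        res = assoc.fit_adjusted(y, x, age, race, eth)
        assert not res.converged
        assert res.beta > 0  # diverging direction preserved

    def test_constant_exposure_nonconverged(self, rng):
        y, x, age, race, eth = simulate_unconfounded(rng, n=500)
        res = assoc.fit_adjusted(y, np.ones_like(y), age, race, eth)
        assert not res.converged

    def test_one_class_outcome_rejected(self, rng):
        y, x, age, race, eth = simulate_unconfounded(rng, n=100)
        with pytest.raises(ValueError, match="case and one control"):
            assoc.fit_adjusted(np.ones_like(y), x, age, race, eth)

    def test_singular_design_names_columns(self, rng):
        y, x, age, race, eth = simulate_unconfounded(rng, n=500)
        with pytest.raises(ValueError, match="collinear"):
            assoc.build_design(age, race, race)  # ethnicity duplicates race


class TestRunPhewas:
    def test_sweep_on_generated_center(self, small_matrix):
        res = assoc.run_phewas(small_matrix)
        assert len(res) == len(small_matrix.phecodes)
        assert res["p_adj"].dropna().between(0, 1).all()
        # strong planted positives and negatives recovered
        by_code = res.set_index("phecode")
        assert by_code.loc["628", "direction"] == "positive"
        assert by_code.loc["650", "direction"] == "negative"

    def test_direction_classification_consistent(self, small_matrix):
        res = assoc.run_phewas(small_matrix)
        sig = res[(res["direction"] != "null")]
        assert ((sig["p_adj"] < 0.05)).all()
        assert ((sig["or_value"] > 1) == (sig["direction"] == "positive")).all()

    def test_redaction_bounds_without_reclassification(self, small_matrix):
        res = assoc.run_phewas(small_matrix, spec=ModelSpec(redaction_threshold=10))
        small = res[res["redacted"]]
        assert len(small) > 0
        assert set(small["or_display"]) <= {">1", "<1"}
        assert set(small["p_display"]) <= {"<0.05", ">=0.05"}
        res_unredacted = assoc.run_phewas(small_matrix, spec=ModelSpec(redaction_threshold=0))
        pd.testing.assert_series_equal(res["direction"], res_unredacted["direction"])

    def test_format_for_export_masks_redacted(self, small_matrix):
        res = assoc.run_phewas(small_matrix)
        out = assoc.format_for_export(res)
        masked = out[out["redacted"]]
        assert masked["or_value"].isna().all()
        assert masked["p"].isna().all()
        visible = out[~out["redacted"]]
        assert visible["or_value"].notna().all()


def test_phewas_frame_matches_fit_adjusted(rng):
    panel = [synth.DiagnosisSpec("626.4", "626.4", "N92.6", "genitourinary", 0.1, 2.0)]
    frame = synth.simulate_case_control(rng, 500, 1500, panel)
    sweep = assoc.phewas_frame(frame)
    direct = assoc.fit_adjusted(
        frame["y"], frame["dx_626.4"], frame["age"], frame["race"], frame["ethnicity"]
    )
    assert sweep.loc[0, "beta"] == pytest.approx(direct.beta, abs=1e-10)
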
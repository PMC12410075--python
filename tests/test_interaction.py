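"""Additive (RERI/AP/S) and multiplicative interaction machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import strokerecur as sr
from strokerecur.cohort import OutcomeModel, simulate_binary_factors
from strokerecur.interaction import (
    AdditiveIndices,
    JointExposureFit,
    additive_indices,
    bootstrap_ci,
    classify_additive,
    collinearity_screen,
    cross_classify,
    delta_ci,
    fit_joint_logistic,
    fit_main_effects,
    fit_three_way,
    multilevel_contrasts,
    two_way_report,
)


def _expand_counts(counts):
    """Patient-level vectors from a 2x2x2 count table [a, b, y]."""
    a, b, y = [], [], []
    for i in range(2):
        for j in range(2):
            for k in range(2):
                a += [i] * counts[i][j][k]
                b += [j] * counts[i][j][k]
                y += [k] * counts[i][j][k]
    return np.array(a), np.array(b), np.array(y)


class TestCrossClassify:
    def test_published_age_stratum_counts(self):
        # strata (model, age): mild/moderate-severe = 47/25, 28/36, 27/37, 24/48
        counts = [[[47, 25], [28, 36]], [[27, 37], [24, 48]]]
        a, b, y = _expand_counts(counts)
        table = cross_classify(a, b, y)
        assert table.sum() == 272
        assert table.tolist() == counts

    def test_degenerate_all_zero(self):
        table = cross_classify([0, 0, 0], [0, 0, 0], [0, 0, 0])
        assert table[0, 0, 0] == 3 and table.sum() == 3

    def test_swap_transposes(self):
        rng = np.random.default_rng(0)
        a, b, y = rng.integers(0, 2, (3, 50))
        assert np.array_equal(
            cross_classify(a, b, y), cross_classify(b, a, y).transpose(1, 0, 2)
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            cross_classify([0, 1], [0], [1, 0])


class TestJointLogistic:
    def test_crude_ors_equal_cross_product_ratios(self, joint_df):
        fit = fit_joint_logistic(joint_df, "a", "b")
        t = cross_classify(joint_df["a"], joint_df["b"], joint_df["recurrence_binary"])

        def cpr(i, j):
            return (t[i, j, 1] * t[0, 0, 0]) / (t[i, j, 0] * t[0, 0, 1])

        assert fit.or10 == pytest.approx(cpr(1, 0), abs=1e-6)
        assert fit.or01 == pytest.approx(cpr(0, 1), abs=1e-6)
        assert fit.or11 == pytest.approx(cpr(1, 1), abs=1e-6)

    def test_large_sample_recovery(self):
        df = sr.simulate_joint_exposure(200_000, or10=2.0, or01=1.5, or11=3.5, seed=1)
        fit = fit_joint_logistic(df, "a", "b")
        assert fit.or10 == pytest.approx(2.0, rel=0.05)
        assert fit.or01 == pytest.approx(1.5, rel=0.05)
        assert fit.or11 == pytest.approx(3.5, rel=0.05)

    def test_null_ors_near_one(self):
        df = sr.simulate_joint_exposure(50_000, or10=1.0, or01=1.0, or11=1.0, seed=2)
        fit = fit_joint_logistic(df, "a", "b")
        for v in (fit.or10, fit.or01, fit.or11):
            assert v == pytest.approx(1.0, abs=0.08)

    def test_empty_cell_named(self):
        df = pd.DataFrame(
            {"a": [0, 0, 1, 1], "b": [0, 1, 0, 0], "recurrence_binary": [0, 1, 0, 1]}
        )
        with pytest.raises(ValueError, match=r"a=1, b=1"):
            fit_joint_logistic(df, "a", "b")

    def test_nonbinary_exposure_rejected(self, joint_df):
        df = joint_df.assign(a=joint_df["a"] + 1)
        with pytest.raises(ValueError, match="binary"):
            fit_joint_logistic(df, "a", "b")


class TestAdditiveIndices:
    def test_exact_additivity(self):
        ind = additive_indices((2.0, 3.0, 4.0))
        assert ind.reri == pytest.approx(0.0, abs=1e-15)
        assert ind.ap == pytest.approx(0.0, abs=1e-15)
        assert ind.s == pytest.approx(1.0)

    def test_null_model_s_undefined(self):
        ind = additive_indices((1.0, 1.0, 1.0))
        assert ind.reri == 0.0 and ind.ap == 0.0
        assert np.isnan(ind.s)
        assert any("S undefined" in n for n in ind.notes)

    def test_published_or_triple_hand_arithmetic(self):
        # ORs as printed for the age stratum; indices by the canonical formulas
        ind = additive_indices((0.890, 0.876, 0.973))
        assert ind.reri == pytest.approx(0.207, abs=1e-12)
        assert ind.s == pytest.approx(0.1154, abs=1e-4)

    @given(
        st.tuples(
            st.floats(0.1, 10.0), st.floats(0.1, 10.0), st.floats(0.1, 10.0)
        )
    )
    def test_matches_arithmetic_oracle(self, ors):
        or10, or01, or11 = ors
        ind = additive_indices((or10, or01, or11))
        assert ind.reri == pytest.approx(or11 - or10 - or01 + 1.0, abs=1e-12)
        assert ind.ap == pytest.approx((or11 - or10 - or01 + 1.0) / or11, abs=1e-12)
        denom = or10 + or01 - 2.0
        if denom != 0:
            assert ind.s == pytest.approx((or11 - 1.0) / denom, abs=1e-9)


class TestDeltaCI:
    def _fit(self, ors, cov):
        or10, or01, or11 = ors
        return JointExposureFit(
            or10=or10, or01=or01, or11=or11,
            params=np.log(ors), cov=np.asarray(cov, dtype=float), n=0,
        )

    def test_zero_covariance_collapses_to_point(self):
        fit = self._fit((2.0, 1.5, 3.5), np.zeros((3, 3)))
        for index, point in (("RERI", 1.0), ("AP", 1.0 / 3.5)):
            lo, hi = delta_ci(fit, index)
            assert lo == pytest.approx(point) and hi == pytest.approx(point)
        lo, hi = delta_ci(fit, "S")
        s = 2.5 / 1.5
        assert lo == pytest.approx(s) and hi == pytest.approx(s)

    def test_delta_vs_bootstrap_agreement(self, joint_df):
        fit = fit_joint_logistic(joint_df, "a", "b")
        d = delta_ci(fit, "RERI")
        b = bootstrap_ci(joint_df, "a", "b", "RERI", n_boot=400, seed=42)
        assert (d[1] - d[0]) == pytest.approx(b[1] - b[0], rel=0.15)

    def test_undefined_s_rejected(self):
        fit = self._fit((1.0, 1.0, 1.0), np.eye(3) * 0.01)
        with pytest.raises(ValueError, match="S undefined"):
            delta_ci(fit, "S")


class TestBootstrapCI:
    def test_determinism(self, joint_df):
        a = bootstrap_ci(joint_df, "a", "b", "RERI", n_boot=150, seed=5)
        b = bootstrap_ci(joint_df, "a", "b", "RERI", n_boot=150, seed=5)
        assert a == b

    def test_constant_outcome_refused(self):
        df = pd.DataFrame(
            {"a": [0, 1] * 50, "b": [0, 0, 1, 1] * 25, "recurrence_binary": [1] * 100}
        )
        with pytest.raises(ValueError):
            bootstrap_ci(df, "a", "b", "RERI", n_boot=100, seed=0)

    def test_width_shrinks_with_n(self):
        small = sr.simulate_joint_exposure(1000, or10=2.0, or01=1.5, or11=3.0, seed=8)
        large = sr.simulate_joint_exposure(4000, or10=2.0, or01=1.5, or11=3.0, seed=8)
        w_small = np.diff(bootstrap_ci(small, "a", "b", "RERI", n_boot=200, seed=1))[0]
        w_large = np.diff(bootstrap_ci(large, "a", "b", "RERI", n_boot=200, seed=1))[0]
        assert 0.3 < w_large / w_small < 0.75  # ~1/2 expected from 1/sqrt(n)

    def test_small_n_boot_rejected(self, joint_df):
        with pytest.raises(ValueError, match=">= 100"):
            bootstrap_ci(joint_df, "a", "b", "RERI", n_boot=50)


class TestClassifyAdditive:
    def test_published_smoking_row_is_antagonism_via_ap(self):
        ind = AdditiveIndices(
            reri=-0.016, ap=-2.231, s=-0.038,
            ci_reri=(-0.3711, 0.1391),
            ci_ap=(-20.5125, -1.4959),
            ci_s=(-0.9372, 0.6836),
        )
        call = classify_additive(ind)
        assert call.verdict == "antagonism"
        assert "AP" in call.triggers

    def test_all_three_trigger_synergy(self):
        ind = AdditiveIndices(
            reri=0.5, ap=0.2, s=1.5,
            ci_reri=(0.1, 0.9), ci_ap=(0.05, 0.4), ci_s=(1.1, 2.0),
        )
        call = classify_additive(ind)
        assert call.verdict == "synergy"
        assert set(call.triggers) == {"RERI", "AP", "S"}

    def test_all_cis_span_null(self):
        ind = AdditiveIndices(
            reri=0.5, ap=0.2, s=1.5,
            ci_reri=(-0.1, 0.9), ci_ap=(-0.05, 0.4), ci_s=(0.9, 2.0),
        )
        assert classify_additive(ind).verdict == "none"

    def test_conflicting_directions_yield_none(self):
        ind = AdditiveIndices(
            reri=0.5, ap=-0.2, s=float("nan"),
            ci_reri=(0.1, 0.9), ci_ap=(-0.4, -0.05), ci_s=None,
        )
        call = classify_additive(ind)
        assert call.verdict == "none"
        assert "conflicting" in call.note

    def test_undefined_s_cannot_trigger(self):
        ind = AdditiveIndices(
            reri=0.0, ap=0.0, s=float("nan"),
            ci_reri=(-0.1, 0.1), ci_ap=(-0.1, 0.1), ci_s=None,
        )
        assert classify_additive(ind).verdict == "none"


class TestMultilevelContrasts:
    @staticmethod
    def _cohort_with_levels(n=4000, seed=3):
        rng = np.random.default_rng(seed)
        code = rng.integers(0, 2, n)
        size = rng.integers(0, 3, n)
        lp = -0.5 + 0.4 * code + 0.5 * size
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
        return pd.DataFrame({"score_code": code, "infarct_size": size, "recurrence_binary": y})

    def test_three_levels_give_three_contrasts(self):
        res = multilevel_contrasts(self._cohort_with_levels(), "score_code", "infarct_size")
        assert [label for label, _ in res] == ["1v0", "2v0", "2v1"]
        for _, ind in res:
            assert ind.ci_reri is not None

    def test_two_levels_reduce_to_binary_path(self):
        df = self._cohort_with_levels()
        df = df[df["infarct_size"] < 2]
        res = multilevel_contrasts(df, "score_code", "infarct_size")
        assert len(res) == 1
        direct = additive_indices(
            fit_joint_logistic(
                df.assign(_contrast=(df["infarct_size"] == 1).astype(int)),
                "score_code", "_contrast",
            )
        )
        assert res[0][1].reri == pytest.approx(direct.reri)


class TestMainEffects:
    def test_or_is_exp_estimate(self, joint_df):
        table = fit_main_effects(joint_df, ["a", "b"])
        assert np.allclose(table["or"], np.exp(table["estimate"]), atol=1e-12)

    def test_known_coefficient_recovered(self):
        m = OutcomeModel(intercept=-0.5, main_effects={"x": 0.3, "z": -0.2})
        df = simulate_binary_factors(20_000, {"x": 0.5, "z": 0.4}, m, seed=13)
        table = fit_main_effects(df, ["x", "z"])
        row = table.loc["x"]
        assert np.log(row["ci_lower"]) <= 0.3 <= np.log(row["ci_upper"])

    def test_separation_rejected(self):
        df = pd.DataFrame({"x": [0] * 20 + [1] * 20, "recurrence_binary": [0] * 20 + [1] * 20})
        with pytest.raises(ValueError):
            fit_main_effects(df, ["x"])


class TestThreeWay:
    def test_collinear_duplicate_factor_rejected(self):
        m = OutcomeModel(intercept=-0.2, main_effects={"a": 0.3, "b": 0.3})
        df = simulate_binary_factors(2000, {"a": 0.5, "b": 0.5}, m, seed=4)
        df["c"] = df["b"]
        with pytest.raises(ValueError, match="empty joint cell|rank deficient|collinear"):
            fit_three_way(df, "a", "b", "c")

    def test_empty_joint_cell_named(self):
        df = pd.DataFrame(
            {
                "a": [0, 0, 0, 0, 1, 1, 1, 1] * 5,
                "b": [0, 0, 1, 1, 0, 0, 1, 1] * 5,
                "c": [0, 1, 0, 1, 0, 1, 0, 0] * 5,  # (1,1,1) never occurs
                "recurrence_binary": [0, 1] * 20,
            }
        )
        with pytest.raises(ValueError, match=r"a=1, b=1, c=1"):
            fit_three_way(df, "a", "b", "c")

    def test_full_factorial_terms_present(self):
        m = OutcomeModel(
            intercept=-0.5,
            main_effects={"a": 0.4, "b": 0.4, "c": 0.4},
            triple_terms={("a", "b", "c"): 0.8},
        )
        df = simulate_binary_factors(5000, {"a": 0.5, "b": 0.5, "c": 0.5}, m, seed=6)
        fit = fit_three_way(df, "a", "b", "c")
        assert list(fit.table.index) == [
            "a", "b", "c", "a*b", "a*c", "b*c", "a*b*c"
        ]
        assert np.allclose(fit.table["or"], np.exp(fit.table["estimate"]), atol=1e-12)
        assert fit.triple_term == "a*b*c"


class TestCollinearityScreen:
    def test_independent_variables_vif_near_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(5000, 4)), columns=list("wxyz"))
        vif, corr = collinearity_screen(df, list("wxyz"))
        assert ((vif >= 1.0) & (vif <= 1.1)).all()
        assert np.allclose(np.diag(corr), 1.0)

    def test_duplicate_variable_flagged_unbounded(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": rng.normal(size=200)})
        df["y"] = df["x"]
        vif, _ = collinearity_screen(df, ["x", "y"])
        assert (vif > 1e6).all() or np.isinf(vif).all()

    def test_constant_variable_flagged(self):
        df = pd.DataFrame({"x": np.ones(100), "y": np.arange(100.0)})
        with pytest.warns(UserWarning, match="constant"):
            vif, _ = collinearity_screen(df, ["x", "y"])
        assert np.isnan(vif["x"])


def test_two_way_report_bundles_everything(joint_df):
    rep = two_way_report(joint_df, "a", "b")
    assert rep["counts"].sum() == len(joint_df)
    assert rep["call"].verdict in {"synergy", "antagonism", "none"}
    assert rep["or_table"].shape == (3, 3)
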
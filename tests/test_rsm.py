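import json

import numpy as np
import pytest

from stentopt.design_space import BoundsError, DOE2_SPACE, StentDesign, TABLE1_SPACE, RESPONSES
from stentopt.doe import DOETable, generate_ccd
from stentopt.rsm import (
    ModelError,
    ModelTerm,
    QuadraticModel,
    build_design_matrix,
    critical_t,
    eq5_terms,
    fit,
    full_quadratic_terms,
    interaction,
    intercept,
    linear,
    quadratic,
    reduce_model,
    residual_diagnostics,
    screen_terms,
    screen_union,
)
from stentopt.surrogate import simulate_responses


def normal_equations(X, y):
    """Brute-force OLS oracle: explicit (XᵀX)⁻¹Xᵀy."""
    return np.linalg.inv(X.T @ X) @ X.T @ y


class TestDesignMatrix:
    def test_full_quadratic_column_counts(self):
        assert len(full_quadratic_terms(("w", "t", "NS", "LA", "SA"))) == 21
        assert len(full_quadratic_terms(("w", "t", "SA"))) == 10
        assert len(eq5_terms()) == 11

    def test_unknown_factor_rejected(self):
        with pytest.raises(ModelError, match="unknown factor"):
            build_design_matrix({"w": np.ones(3)}, [intercept(), linear("q")])

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ModelError, match="duplicate"):
            build_design_matrix({"w": np.ones(3)}, [linear("w"), linear("w")])

    def test_term_kinds_validated(self):
        with pytest.raises(ModelError):
            ModelTerm("interaction", ("w", "w"))
        with pytest.raises(ModelError):
            ModelTerm("cubic", ("w",))


class TestFit:
    def test_ols_matches_normal_equations_oracle(self, table4):
        from stentopt.rsm import _factor_values

        for m in RESPONSES:
            model = fit(table4, m.key, eq5_terms())
            X = build_design_matrix(_factor_values(table4, "natural"), model.terms)
            beta_oracle = normal_equations(X, table4.response(m.key))
            assert np.max(np.abs(model.beta - beta_oracle)) < 1e-8

    def test_fitted_values_reproduce_xbeta(self, doe1_models):
        from stentopt.rsm import _factor_values

        for model in doe1_models.values():
            X = build_design_matrix(model.train_values, model.terms)
            assert np.max(np.abs(X @ model.beta - model.fitted)) < 1e-9

    def test_noiseless_quadratic_recovered_exactly(self, interior_truth):
        plan = generate_ccd(TABLE1_SPACE)
        table = simulate_responses(plan.designs(), interior_truth.noiseless(), seed=0)
        for key, beta_true in interior_truth.beta.items():
            model = fit(table, key, list(interior_truth.terms[key]))
            assert np.max(np.abs(model.beta - beta_true)) < 1e-6

    def test_r2_non_decreasing_in_nested_terms(self, table4):
        rng = np.random.default_rng(7)
        all_terms = full_quadratic_terms(TABLE1_SPACE.names)
        for _ in range(10):
            size = rng.integers(1, 15)
            idx = rng.choice(len(all_terms) - 1, size=size, replace=False) + 1
            small = [all_terms[0]] + [all_terms[i] for i in sorted(idx)]
            extra = next(t for t in all_terms if t not in small)
            large = small + [extra]
            r_small = fit(table4, "mean_stress", small).r_squared
            r_large = fit(table4, "mean_stress", large).r_squared
            assert r_large >= r_small - 1e-12

    def test_rank_deficiency_reported(self, table5):
        # duplicating w as t makes the two linear columns collinear
        frame = table5.frame.copy()
        frame["t_um"] = frame["w_um"]
        dup = DOETable(space=DOE2_SPACE, frame=frame)
        with pytest.raises(ModelError, match="rank-deficient"):
            fit(dup, "mean_stress", [intercept(), linear("w"), linear("t")])

    def test_too_few_runs_rejected(self, table5):
        tiny = DOETable(space=DOE2_SPACE, frame=table5.frame.iloc[:5])
        with pytest.raises(ModelError):
            fit(tiny, "mean_stress", "full")

    def test_coded_and_natural_fits_predict_identically(self, table4):
        d = StentDesign(w=130, t=220, NS=20, LA=0.2, SA=1.0)
        nat = fit(table4, "apposition", eq5_terms(), units="natural")
        cod = fit(table4, "apposition", eq5_terms(), units="coded")
        assert nat.predict(d) == pytest.approx(cod.predict(d), abs=1e-8)


class TestScreening:
    def test_critical_t_from_residual_df(self, table4):
        full = fit(table4, "mean_stress", "full", units="coded")
        assert full.df_resid == 43 - 21 == 22
        assert critical_t(22) == pytest.approx(2.0739, abs=1e-3)

    def test_fixed_threshold_mode(self, table4):
        full = fit(table4, "mean_stress", "full", units="coded")
        _, diag = screen_terms(full, t_crit=2.04)
        assert diag.t_crit == 2.04

    def test_union_of_screened_terms_is_reduced_set(self, table4):
        """Per-response screening unioned over the four responses yields
        exactly the ten-term reduced model of the five-factor study."""
        union = screen_union(table4)
        assert [t.label for t in union] == [t.label for t in eq5_terms()]

    def test_la_terms_all_dropped(self, table4):
        union = screen_union(table4)
        assert not any("LA" in t.factors for t in union)

    def test_single_strong_effect_dominates(self, interior_truth):
        """A lone strong linear effect survives screening; pure-noise terms
        are (almost) all dropped."""
        rng = np.random.default_rng(3)
        plan = generate_ccd(TABLE1_SPACE)
        designs = plan.designs()
        w = np.array([d.w for d in designs])
        y = 50.0 + 0.1 * w + rng.normal(0, 0.5, len(designs))  # |t| >> 10 on w
        frame = simulate_responses(designs, interior_truth.noiseless(), seed=0).frame.copy()
        frame["mean_stress_kPa"] = y
        table = DOETable(space=TABLE1_SPACE, frame=frame)
        full = fit(table, "mean_stress", "full", units="coded")
        kept, diag = screen_terms(full)
        assert diag.significant["w"]
        spurious = [t for t in kept if t.kind != "intercept" and t.factors != ("w",)]
        assert len(spurious) <= 2  # ~1 false positive expected at alpha=0.05

    def test_constant_response_keeps_intercept_only(self, interior_truth):
        rng = np.random.default_rng(5)
        plan = generate_ccd(TABLE1_SPACE)
        designs = plan.designs()
        frame = simulate_responses(designs, interior_truth.noiseless(), seed=0).frame.copy()
        frame["pinching"] = 1.5 + rng.normal(0, 0.01, len(designs))
        table = DOETable(space=TABLE1_SPACE, frame=frame)
        kept, diag = screen_terms(fit(table, "pinching", "full", units="coded"))
        assert intercept() in kept
        # at alpha=0.05 a couple of the 20 noise terms may clear the bar
        # (heredity can then add their linear parents)
        n_spurious = sum(diag.significant[t.label] for t in kept if t.kind != "intercept")
        assert n_spurious <= 2

    def test_hierarchy_restores_linear_parents(self, interior_truth):
        # response driven purely by the w*SA interaction
        plan = generate_ccd(TABLE1_SPACE)
        designs = plan.designs()
        rng = np.random.default_rng(11)
        w = np.array([d.w for d in designs])
        sa = np.array([d.SA for d in designs])
        frame = simulate_responses(designs, interior_truth.noiseless(), seed=0).frame.copy()
        frame["mean_stress_kPa"] = 30 + 0.05 * (w - 175) * (sa - 1.25) + rng.normal(0, 0.3, len(designs))
        table = DOETable(space=TABLE1_SPACE, frame=frame)
        kept, _ = screen_terms(fit(table, "mean_stress", "full", units="coded"))
        assert interaction("w", "SA") in kept
        assert linear("w") in kept and linear("SA") in kept

    def test_zero_residual_variance_rejected(self, interior_truth):
        plan = generate_ccd(TABLE1_SPACE)
        table = simulate_responses(plan.designs(), interior_truth.noiseless(), seed=0)
        exact = fit(table, "mean_stress", "full", units="coded")
        with pytest.raises(ModelError, match="zero residual variance"):
            screen_terms(exact)


class TestPredict:
    def test_extrapolation_rejected_by_default(self, doe1_models):
        outside = StentDesign(w=300, t=175, NS=24, LA=0.4, SA=1.25)
        model = doe1_models["mean_stress"]
        with pytest.raises(BoundsError):
            model.predict(outside)
        assert np.isfinite(model.predict(outside, extrapolate=True))

    def test_intercept_only_model_is_constant(self, table4):
        model = fit(table4, "pinching", [intercept()])
        d1 = TABLE1_SPACE.to_natural([1, 1, 1, 1, 1])
        d2 = TABLE1_SPACE.to_natural([-1, 0, 1, 0, -1])
        assert model.predict(d1) == model.predict(d2) == pytest.approx(model.beta[0])

    def test_json_round_trip_preserves_predictions(self, doe1_models, tmp_path):
        model = doe1_models["apposition"]
        p = tmp_path / "m.json"
        model.to_json(p)
        clone = QuadraticModel.from_json(p)
        d = StentDesign(w=100, t=100, NS=16, LA=0.8, SA=0.5)
        assert clone.predict(d) == pytest.approx(model.predict(d), abs=1e-12)
        assert clone.r_squared == model.r_squared


class TestDiagnostics:
    def test_normal_residuals_rarely_rejected(self, table4, interior_truth):
        """Shapiro–Wilk on residuals holds its size under normal noise."""
        plan = generate_ccd(TABLE1_SPACE)
        designs = plan.designs()
        base = simulate_responses(designs, interior_truth.noiseless(), seed=0).frame
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            frame = base.copy()
            frame["mean_stress_kPa"] = frame["mean_stress_kPa"] + rng.normal(0, 1.0, len(frame))
            table = DOETable(space=TABLE1_SPACE, frame=frame)
            model = fit(table, "mean_stress", eq5_terms())
            diag = residual_diagnostics(model)
            ok += diag.shapiro_p > 0.05
        assert ok >= 90

    def test_heavy_tailed_residuals_usually_rejected(self, table4, interior_truth):
        plan = generate_ccd(TABLE1_SPACE)
        designs = plan.designs()
        base = simulate_responses(designs, interior_truth.noiseless(), seed=0).frame
        rejected = 0
        n_rep = 50
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            frame = base.copy()
            noise = rng.standard_cauchy(len(frame))
            frame["mean_stress_kPa"] = np.abs(frame["mean_stress_kPa"] + noise)
            table = DOETable(space=TABLE1_SPACE, frame=frame)
            model = fit(table, "mean_stress", eq5_terms())
            diag = residual_diagnostics(model)
            rejected += diag.shapiro_p < 0.05
        assert rejected > n_rep / 2

    def test_levene_reported_per_factor(self, doe1_models):
        diag = residual_diagnostics(doe1_models["mean_stress"])
        assert set(diag.levene_by_factor) == set(TABLE1_SPACE.names)
        assert 0 <= diag.levene_p <= 1
        assert diag.levene_factor in TABLE1_SPACE.names

    def test_few_residuals_skips_with_warning(self, table5):
        model = fit(table5, "pinching", [intercept(), linear("w")])
        model.residuals = model.residuals[:5]
        with pytest.warns(UserWarning, match="skipped"):
            diag = residual_diagnostics(model)
        assert diag.shapiro_p is None


class TestReduceModel:
    def test_doe2_apposition_reduction(self, table5):
        model, diag = reduce_model(table5, "apposition")
        labels = {t.label for t in model.terms}
        assert "1" in labels
        assert len(model.terms) < 10
        assert diag.t_crit == pytest.approx(critical_t(5), abs=1e-9)
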
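import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stentopt.design_space import DOE2_SPACE, StentDesign, TABLE1_SPACE
from stentopt.optimize import (
    ResponseGoal,
    SpecError,
    composite,
    desirability,
    default_spec,
    optimize_designs,
    predicted_ranges,
    sensitivity_contributions,
)
from stentopt.rsm import QuadraticModel, intercept, linear, reduce_model


def linear_model(space, response, beta0, slopes):
    """Hand-built linear QuadraticModel in natural units."""
    terms = [intercept()] + [linear(n) for n in slopes]
    beta = np.array([beta0] + list(slopes.values()), dtype=float)
    n = len(beta)
    return QuadraticModel(
        response=response,
        terms=terms,
        beta=beta,
        se=np.zeros(n),
        tvalues=np.zeros(n),
        df_resid=1,
        r_squared=1.0,
        space=space,
        units="natural",
        residuals=np.zeros(2),
        fitted=np.zeros(2),
    )


class TestDesirability:
    def test_stb_is_one_at_lower_anchor(self):
        g = ResponseGoal("STB", 10.0, 50.0)
        assert desirability(10.0, g) == 1.0
        assert desirability(5.0, g) == 1.0
        assert desirability(50.0, g) == 0.0

    def test_ltb_is_one_at_upper_anchor(self):
        g = ResponseGoal("LTB", 10.0, 50.0)
        assert desirability(50.0, g) == 1.0
        assert desirability(60.0, g) == 1.0
        assert desirability(10.0, g) == 0.0

    def test_midpoint_gives_half_either_direction(self):
        for direction in ("STB", "LTB"):
            assert desirability(30.0, ResponseGoal(direction, 10.0, 50.0)) == 0.5

    def test_invalid_anchors_rejected(self):
        with pytest.raises(SpecError):
            ResponseGoal("STB", 5.0, 5.0)
        with pytest.raises(SpecError):
            ResponseGoal("up", 0.0, 1.0)

    @settings(deadline=None, derandomize=True)
    @given(
        y1=st.floats(0, 100),
        y2=st.floats(0, 100),
        direction=st.sampled_from(["STB", "LTB"]),
    )
    def test_monotone_in_predicted_value(self, y1, y2, direction):
        g = ResponseGoal(direction, 20.0, 80.0)
        lo, hi = sorted([y1, y2])
        if direction == "LTB":
            assert desirability(hi, g) >= desirability(lo, g)
        else:
            assert desirability(hi, g) <= desirability(lo, g)


class TestComposite:
    def test_all_ones_gives_one(self):
        assert composite([1.0, 1.0, 1.0, 1.0]) == 1.0

    def test_any_zero_collapses(self):
        assert composite([0.0, 1.0, 0.5, 1.0]) == 0.0

    def test_equal_weights_is_plain_product(self):
        assert composite([0.25, 1.0, 1.0, 1.0]) == 0.25

    def test_weighted_geometric_mean(self):
        d = np.array([0.25, 0.5])
        w = [3.0, 1.0]
        expected = (0.25**3 * 0.5) ** (1 / 4)
        assert composite(d, w) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(SpecError):
            composite([1.2, 0.5])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=6))
    def test_product_never_exceeds_minimum(self, ds):
        assert composite(ds) <= min(ds) + 1e-15


class TestOptimizer:
    def test_monotone_ltb_model_optimum_at_upper_corner(self):
        models = {"apposition": linear_model(DOE2_SPACE, "apposition", 0.0, {"w": 0.1, "t": 0.1, "SA": 10.0})}
        res = optimize_designs(models, DOE2_SPACE, grid=11)
        assert (res.design.w, res.design.t, res.design.SA) == (150.0, 150.0, 0.7)
        assert res.composite_d == pytest.approx(1.0)

    def test_opposed_stb_responses_balance(self):
        models = {
            "mean_stress": linear_model(DOE2_SPACE, "mean_stress", 50.0, {"w": 0.2}),
            "pinching": linear_model(DOE2_SPACE, "pinching", 1.5, {"w": -0.002}),
        }
        res = optimize_designs(models, DOE2_SPACE, grid=21)
        # equal and opposite normalized slopes -> interior compromise in w
        assert res.per_response_d["mean_stress"] == pytest.approx(res.per_response_d["pinching"], abs=1e-6)

    def test_result_self_consistent_with_model_predictions(self, doe1_models):
        res = optimize_designs(doe1_models, TABLE1_SPACE, grid=11)
        for key, model in doe1_models.items():
            assert res.predicted[key] == pytest.approx(model.predict(res.design), abs=1e-9)
        d_prod = np.prod(list(res.per_response_d.values()))
        assert res.composite_d == pytest.approx(d_prod, abs=1e-12)

    def test_ns_reported_as_even_integer(self, doe1_models):
        res = optimize_designs(doe1_models, TABLE1_SPACE, grid=11)
        assert res.design.NS % 2 == 0

    def test_grid_resolution_independence_doe2(self, table5):
        models = {k: reduce_model(table5, k)[0] for k in ("mean_stress", "high_stress_area", "apposition", "pinching")}
        res21 = optimize_designs(models, DOE2_SPACE, grid=21)
        res41 = optimize_designs(models, DOE2_SPACE, grid=41)
        for n in DOE2_SPACE.names:
            f = DOE2_SPACE[n]
            assert abs(res21.design.get(n) - res41.design.get(n)) <= f.range / 10

    def test_flat_axis_detected_for_la(self, doe1_models):
        res = optimize_designs(doe1_models, TABLE1_SPACE, grid=11)
        assert res.trace["flat_axes"] == ["LA"]

    def test_degenerate_spec_warns(self):
        models = {"apposition": linear_model(DOE2_SPACE, "apposition", 0.0, {"w": 1.0})}
        spec = {"apposition": ResponseGoal("LTB", 1e6, 2e6)}  # unreachable
        with pytest.warns(UserWarning, match="zero everywhere"):
            res = optimize_designs(models, DOE2_SPACE, spec=spec, grid=5, polish=False)
        assert res.composite_d == 0.0


class TestRanges:
    def test_predicted_ranges_bound_grid_predictions(self, doe1_models):
        ranges = predicted_ranges(doe1_models, TABLE1_SPACE, grid=11)
        for key, model in doe1_models.items():
            lo, hi = ranges[key]
            assert lo < hi
            center = model.predict(TABLE1_SPACE.midpoint_design())
            assert lo - 1e-9 <= center <= hi + 1e-9

    def test_observed_mode_uses_table_extremes(self, doe1_models, table4):
        spec = default_spec(
            doe1_models,
            TABLE1_SPACE,
            range_mode="observed",
            observed={k: table4.response(k) for k in doe1_models},
        )
        assert spec["mean_stress"].y_min == table4.response("mean_stress").min()
        assert spec["apposition"].direction == "LTB"
        assert spec["pinching"].direction == "STB"


class TestSensitivity:
    def test_single_factor_model_contributes_everything(self):
        models = {"mean_stress": linear_model(DOE2_SPACE, "mean_stress", 10.0, {"w": 0.3})}
        rep = sensitivity_contributions(models, DOE2_SPACE)
        c = rep.contributions("mean_stress")
        assert c["w"] == pytest.approx(100.0)
        assert c["t"] == 0.0 and c["SA"] == 0.0

    def test_equal_slope_equal_range_split_evenly(self):
        models = {"mean_stress": linear_model(DOE2_SPACE, "mean_stress", 10.0, {"w": 0.3, "t": 0.3})}
        c = sensitivity_contributions(models, DOE2_SPACE).contributions("mean_stress")
        assert c["w"] == pytest.approx(50.0) and c["t"] == pytest.approx(50.0)

    def test_contributions_sum_to_hundred(self, doe1_models):
        rep = sensitivity_contributions(doe1_models, TABLE1_SPACE)
        for key in doe1_models:
            assert rep.contributions(key).sum() == pytest.approx(100.0, abs=1e-9)

    def test_analytic_gradient_matches_finite_differences(self, doe1_models):
        mid = TABLE1_SPACE.midpoint_design()
        for model in doe1_models.values():
            grad = model.gradient(mid)
            for n in TABLE1_SPACE.names:
                h = 1e-6 * TABLE1_SPACE[n].range
                up = mid.with_values(**{n: mid.get(n) + h})
                dn = mid.with_values(**{n: mid.get(n) - h})
                fd = (model.predict(up) - model.predict(dn)) / (2 * h)
                denom = max(abs(fd), 1e-12)
                assert abs(grad[n] - fd) / denom < 1e-5 or abs(grad[n] - fd) < 1e-9

    def test_all_zero_derivatives_rejected(self):
        models = {"mean_stress": linear_model(DOE2_SPACE, "mean_stress", 10.0, {})}
        with pytest.raises(SpecError, match="vanish"):
            sensitivity_contributions(models, DOE2_SPACE)
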
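"""Batch fitting, compilation and sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest

from leafphys.co2_light import fit_aci_response, fit_aq_response
from leafphys.fitting import FitResult
from leafphys.meta import analyze_sensitivity, compile_data, compute_sensitivity, fit_many
from leafphys.synth import CurveDesign, generate_synthetic_curve


@pytest.fixture
def four_aq_curves():
    frames = []
    for i, leaf in enumerate(["L1", "L2", "L3", "L4"]):
        t = generate_synthetic_curve(CurveDesign(kind="aq", noise_sd=0.2, seed=10 + i))
        t["leaf_id"] = leaf
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


class TestFitMany:
    def test_one_result_per_group(self, four_aq_curves):
        out = fit_many(four_aq_curves, "leaf_id", fit_aq_response)
        assert len(out.fits) == 4
        assert not out.failures

    def test_failure_isolation(self, four_aq_curves):
        corrupted = four_aq_curves[
            (four_aq_curves["leaf_id"] != "L2") | (four_aq_curves["Q"] > 1000)]
        out = fit_many(corrupted, "leaf_id", fit_aq_response)
        assert len(out.fits) == 3
        assert "L2" in out.failures

    def test_single_group_matches_direct_call(self, four_aq_curves):
        one = four_aq_curves[four_aq_curves["leaf_id"] == "L1"].reset_index(drop=True)
        direct = fit_aq_response(one)
        grouped = fit_many(one, "leaf_id", fit_aq_response)
        assert grouped.fits["L1"].params == pytest.approx(direct.params)

    def test_missing_group_column_rejected(self, four_aq_curves):
        with pytest.raises(ValueError, match="plot_id"):
            fit_many(four_aq_curves, "plot_id", fit_aq_response)


class TestCompileData:
    def test_parameter_table_one_row_per_group(self, four_aq_curves):
        out = fit_many(four_aq_curves, "leaf_id", fit_aq_response)
        table = compile_data(out, "parameters")
        assert len(table) == 4
        assert {"leaf_id", "A_sat", "phi_J"} <= set(table.columns)

    def test_graphs_selector_yields_figures(self, four_aq_curves):
        out = fit_many(four_aq_curves, "leaf_id", fit_aq_response)
        graphs = compile_data(out, "graphs")
        assert len(graphs) == 4

    def test_unknown_selector_lists_options(self, four_aq_curves):
        out = fit_many(four_aq_curves, "leaf_id", fit_aq_response)
        with pytest.raises(ValueError, match="parameters"):
            compile_data(out, "bogus")


def _toy_fit(data, p=1.0, q=1.0):
    """Fitting-function stand-in whose 'estimate' is an analytic function."""
    return FitResult(model="toy", params={"m": p**2 * q})


class TestSensitivity:
    def test_grid_row_count_is_product(self):
        data = pd.DataFrame({"x": [1.0]})
        table = analyze_sensitivity(_toy_fit, data, ("p", [0.8, 0.9, 1.0, 1.1, 1.2]),
                                    ("q", [0.9, 1.0, 1.1, 1.2]))
        assert len(table) == 20

    def test_single_point_grid_matches_plain_fit(self):
        data = pd.DataFrame({"x": [1.0]})
        table = analyze_sensitivity(_toy_fit, data, ("p", [1.0]))
        assert len(table) == 1
        assert table["m"].iloc[0] == pytest.approx(_toy_fit(data, p=1.0).params["m"])

    def test_identity_output_has_unit_control_coefficient(self):
        def ident(data, p=1.0):
            return FitResult(model="id", params={"m": p})

        table = analyze_sensitivity(ident, pd.DataFrame({"x": [0.0]}),
                                    ("p", [0.5, 1.0, 1.5, 2.0]))
        table = compute_sensitivity(table, {"p": 1.0}, "m")
        off_ref = table[~table["reference"]]
        np.testing.assert_allclose(off_ref["control_coefficient"], 1.0)
        assert np.isnan(table.loc[table["reference"], "control_coefficient"]).all()

    def test_constant_output_has_zero_sensitivity(self):
        def const(data, p=1.0):
            return FitResult(model="c", params={"m": 7.0})

        table = analyze_sensitivity(const, pd.DataFrame({"x": [0.0]}), ("p", [1.0, 2.0, 3.0]))
        table = compute_sensitivity(table, {"p": 1.0}, "m")
        off_ref = table[~table["reference"]]
        np.testing.assert_allclose(off_ref["parameter_effect"], 0.0)
        np.testing.assert_allclose(off_ref["control_coefficient"], 0.0)

    def test_quadratic_elasticity_hand_arithmetic(self):
        def square(data, p=1.0):
            return FitResult(model="sq", params={"m": p**2})

        table = analyze_sensitivity(square, pd.DataFrame({"x": [0.0]}), ("p", [1.0, 1.1]))
        table = compute_sensitivity(table, {"p": 1.0}, "m")
        ce = table.loc[table["p"] == 1.1, "control_coefficient"].iloc[0]
        assert ce == pytest.approx(0.21 / 0.1)

    def test_reference_off_grid_rejected(self):
        table = analyze_sensitivity(_toy_fit, pd.DataFrame({"x": [0.0]}), ("p", [1.0, 2.0]))
        with pytest.raises(ValueError, match="reference"):
            compute_sensitivity(table, {"p": 3.0}, "m")

    def test_three_factors_rejected(self):
        with pytest.raises(TypeError):
            analyze_sensitivity(_toy_fit, pd.DataFrame({"x": [0.0]}),
                                ("p", [1.0]), ("q", [1.0]), ("r", [1.0]))

    def test_two_factor_axis_slice_reproduces_one_factor_run(self):
        data = pd.DataFrame({"x": [0.0]})
        p_vals, q_ref = [0.8, 1.0, 1.3], 1.0
        two = analyze_sensitivity(_toy_fit, data, ("p", p_vals), ("q", [q_ref, 1.2]))
        two = compute_sensitivity(two, {"p": 1.0, "q": q_ref}, "m")
        one = analyze_sensitivity(_toy_fit, data, ("p", p_vals), q=q_ref)
        one = compute_sensitivity(one, {"p": 1.0}, "m")
        axis = two[np.isclose(two["q"], q_ref)].reset_index(drop=True)
        np.testing.assert_allclose(axis["control_coefficient_p"].to_numpy(),
                                   one["control_coefficient"].to_numpy(), equal_nan=True)
        # off-axis rows have no single-factor coefficient
        off_axis = two[~np.isclose(two["q"], q_ref)]
        assert np.isnan(off_axis["control_coefficient_p"]).all()

    def test_failed_grid_point_recorded_not_raised(self):
        def flaky(data, p=1.0):
            if p > 1.5:
                raise RuntimeError("boom")
            return FitResult(model="f", params={"m": p})

        table = analyze_sensitivity(flaky, pd.DataFrame({"x": [0.0]}), ("p", [1.0, 2.0]))
        assert table["failed"].tolist() == [False, True]


class TestAciSensitivity:
    def test_vcmax_responds_to_assumed_gamma_star(self):
        # generate without TPU limitation so the Ci-basis fit is exact at truth
        data = generate_synthetic_curve(CurveDesign(
            kind="aci", noise_sd=0.0, seed=1, true_params={"V_TPU": 1e3}))

        def build(point):
            return {"kinetics": {"Gamma_star25": point["Gamma_star25"]}}

        table = analyze_sensitivity(fit_aci_response, data,
                                    ("Gamma_star25", [38.0, 42.75, 48.0]),
                                    arg_builder=build, fit_tpu=False)
        v = table.set_index("Gamma_star25")["V_cmax"]
        assert v[38.0] != pytest.approx(v[48.0], rel=1e-3)
        assert v[42.75] == pytest.approx(100.0, rel=1e-3)
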
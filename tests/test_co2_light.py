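"""A-Q and A-Ci curve evaluation and fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafphys.co2_light import (
    eval_aq,
    eval_fvcb_ci,
    fit_aci_response,
    fit_aq_response,
    kinetics_at_temperature,
)

AQ = {"A_sat": 25.0, "phi_J": 0.05, "theta_J": 0.85, "R_d": 1.2}


class TestEvalAQ:
    def test_dark_limit_is_minus_respiration(self):
        assert eval_aq(AQ, 0.0) == pytest.approx(-AQ["R_d"])

    def test_saturation_limit(self):
        assert eval_aq(AQ, 1e6) == pytest.approx(AQ["A_sat"] - AQ["R_d"], rel=1e-3)

    def test_double_root_at_theta_one(self):
        # theta=1 and phi*Q = A_sat: the discriminant vanishes, gross = A_sat
        p = {"A_sat": 20.0, "phi_J": 0.05, "theta_J": 1.0, "R_d": 0.0}
        Q = p["A_sat"] / p["phi_J"]
        assert eval_aq(p, Q) == pytest.approx(p["A_sat"])

    def test_theta_zero_rectangular_limit(self):
        p = {**AQ, "theta_J": 0.0}
        Q = 200.0
        expected = p["phi_J"] * Q * p["A_sat"] / (p["phi_J"] * Q + p["A_sat"]) - p["R_d"]
        assert eval_aq(p, Q) == pytest.approx(expected)

    def test_negative_light_rejected(self):
        with pytest.raises(ValueError):
            eval_aq(AQ, -5.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(theta=st.floats(0.05, 1.0), phi=st.floats(0.01, 0.1), asat=st.floats(5.0, 40.0))
    def test_monotone_and_concave_in_light(self, theta, phi, asat):
        p = {"A_sat": asat, "phi_J": phi, "theta_J": theta, "R_d": 1.0}
        Q = np.linspace(0.0, 2000.0, 400)
        A = np.asarray(eval_aq(p, Q))
        diffs = np.diff(A)
        assert np.all(diffs >= -1e-9)          # non-decreasing
        assert np.all(np.diff(diffs) <= 1e-9)  # concave

    def test_gross_term_below_both_asymptotes(self):
        Q = np.linspace(0.0, 3000.0, 50)
        gross = np.asarray(eval_aq(AQ, Q)) + AQ["R_d"]
        assert np.all(gross <= np.minimum(AQ["phi_J"] * Q, AQ["A_sat"]) + 1e-9)


class TestFitAQ:
    def test_noiseless_recovery(self, make_curve):
        data = make_curve("aq")
        res = fit_aq_response(data)
        assert res.success
        for k, v in AQ.items():
            assert res.params[k] == pytest.approx(v, rel=1e-4)

    def test_too_few_points_rejected(self):
        data = pd.DataFrame({"Q": [0.0, 100.0, 1500.0], "A_net": [-1.0, 5.0, 20.0]})
        with pytest.raises(ValueError, match=">= 6"):
            fit_aq_response(data)

    def test_saturating_only_design_flags_phi(self, make_curve):
        data = make_curve("aq", drivers={"Q": [900, 1000, 1100, 1200, 1350, 1500]})
        res = fit_aq_response(data)
        assert any("phi_J" in w for w in res.warnings)

    def test_plot_has_fit_and_band(self, make_curve):
        res = fit_aq_response(make_curve("aq", noise_sd=0.3))
        fig = res.plot()
        assert len(fig.axes) == 1


FVCB = {"V_cmax": 100.0, "J": 160.0, "V_TPU": 12.0, "R_d": 1.5,
        "Gamma_star": 42.0, "K_m": 700.0}


class TestEvalFvCB:
    def test_compensation_point(self):
        out = eval_fvcb_ci(FVCB, FVCB["Gamma_star"])
        assert out["A_c"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["A_j"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["A_mod"].iloc[0] == pytest.approx(-FVCB["R_d"])

    def test_high_co2_asymptote_is_j_over_four(self):
        p = {**FVCB, "V_TPU": 1e6}
        out = eval_fvcb_ci(p, 1e6)
        assert out["A_mod"].iloc[0] == pytest.approx(p["J"] / 4.0 - p["R_d"], rel=1e-3)

    def test_rubisco_rate_hand_arithmetic(self):
        # V_cmax=100, Gamma*=42, K_m=700, C_i=300 -> A_c = 100*258/1000
        out = eval_fvcb_ci(FVCB, 300.0)
        assert out["A_c"].iloc[0] == pytest.approx(25.8)

    def test_min_rule_bounds_every_branch(self):
        C_i = np.linspace(50.0, 1500.0, 40)
        out = eval_fvcb_ci(FVCB, C_i)
        for col in ("A_c", "A_j", "A_p"):
            assert np.all(out["A_mod"] <= out[col] - FVCB["R_d"] + 1e-12)

    def test_limitation_labels_partition_ci_axis(self):
        out = eval_fvcb_ci(FVCB, np.linspace(50.0, 1500.0, 200))
        labels = out["limitation"].to_numpy()
        changes = (labels[1:] != labels[:-1]).sum()
        assert changes <= 2  # at most 3 contiguous segments

    def test_nonpositive_ci_rejected(self):
        with pytest.raises(ValueError):
            eval_fvcb_ci(FVCB, 0.0)


class TestFitACi:
    def test_noiseless_recovery(self, make_curve):
        data = make_curve("aci")
        res = fit_aci_response(data)
        assert res.success
        truth = {"V_cmax": 100.0, "J_max": 180.0, "V_TPU": 12.0, "R_d": 1.5}
        for k, v in truth.items():
            assert res.params[k] == pytest.approx(v, rel=1e-3)

    def test_modelled_table_and_kinetics_reported(self, make_curve):
        res = fit_aci_response(make_curve("aci"))
        mod = res.extra["modelled"]
        assert {"A_c", "A_j", "A_p", "A_mod", "limitation"} <= set(mod.columns)
        assert res.extra["kinetics"]["Gamma_star"] == pytest.approx(
            kinetics_at_temperature(298.15)["Gamma_star"])

    def test_rubisco_only_data_flags_jmax(self, make_curve):
        # low-Ci points only: the whole curve is on the A_c branch
        data = make_curve("aci", drivers={"C_i": [50, 80, 110, 140, 170, 200, 230]})
        res = fit_aci_response(data, fit_tpu=False)
        assert any("J_max" in w for w in res.warnings)

    def test_too_few_points_rejected(self, make_curve):
        data = make_curve("aci").iloc[:4]
        with pytest.raises(ValueError, match=">= 5"):
            fit_aci_response(data)

    def test_nls_beats_coarse_grid_oracle(self, make_curve):
        data = make_curve("aci", noise_sd=0.5, seed=3)
        res = fit_aci_response(data, fit_tpu=False)
        C_i = data["C_i"].to_numpy()
        A = data["A_net"].to_numpy()
        kin = res.extra["kinetics"]
        G, K_m = kin["Gamma_star"], kin["K_m"]
        best = np.inf
        for v in np.linspace(50, 150, 15):
            for j in np.linspace(100, 260, 15):
                for rd in np.linspace(0.0, 4.0, 15):
                    pred = np.minimum(v * (C_i - G) / (C_i + K_m),
                                      j * (C_i - G) / (4 * C_i + 8 * G)) - rd
                    best = min(best, float(np.sum((pred - A) ** 2)))
        assert res.ssr <= best + 1e-9

    def test_confounded_parameters_flagged_by_large_se(self):
        # two perfectly confounded offsets: the SE/estimate > 1 rule must fire
        from leafphys.fitting import fit_multistart

        rng = np.random.default_rng(1)
        y = 5.0 + rng.normal(0, 0.1, 12)

        def predict(p):
            return np.full(12, p["a"] + p["b"])

        res = fit_multistart("toy", predict, y, [{"a": 2.0, "b": 3.0}])
        assert any("unidentifiable" in w or "singular" in w for w in res.warnings)

    def test_mean_temperature_kinetics_adjustment(self, make_curve):
        warm = make_curve("aci", drivers={"T_leaf_C": 35.0})
        res = fit_aci_response(warm)
        assert res.extra["kinetics"]["Gamma_star"] > kinetics_at_temperature(298.15)["Gamma_star"]
        assert res.params["V_cmax"] == pytest.approx(100.0, rel=1e-3)


class TestKinetics:
    def test_bernacchi_reference_values_at_25C(self):
        kin = kinetics_at_temperature(298.15)
        assert kin["Gamma_star"] == pytest.approx(42.75)
        assert kin["K_c"] == pytest.approx(404.9)
        assert kin["K_o"] == pytest.approx(278.4)

    def test_kinetics_increase_with_temperature(self):
        cold, warm = kinetics_at_temperature(288.15), kinetics_at_temperature(308.15)
        assert all(warm[k] > cold[k] for k in ("Gamma_star", "K_c", "K_o"))
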
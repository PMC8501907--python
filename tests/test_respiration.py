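"""Light-respiration estimators and variable-J mesophyll conductance."""

import numpy as np
import pandas as pd
import pytest

from leafphys.respiration import (
    fit_g_mc_variableJ,
    fit_r_light_kok,
    fit_r_light_walker_ort,
    fit_r_light_yin,
)


class TestKok:
    def test_exact_line_recovers_intercept(self):
        Q = np.array([40.0, 60.0, 80.0, 100.0])
        data = pd.DataFrame({"Q": Q, "A_net": 0.04 * Q - 1.0})
        res = fit_r_light_kok(data)
        assert res.R_light == pytest.approx(1.0, abs=1e-12)
        assert res.slope == pytest.approx(0.04, abs=1e-12)

    def test_monte_carlo_mean_within_three_se(self):
        rng = np.random.default_rng(0)
        Q = np.array([40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0])
        estimates, ses = [], []
        for _ in range(200):
            data = pd.DataFrame({"Q": Q, "A_net": 0.04 * Q - 1.0 + rng.normal(0, 0.05, Q.size)})
            res = fit_r_light_kok(data)
            estimates.append(res.R_light)
            ses.append(res.R_light_se)
        assert abs(np.mean(estimates) - 1.0) < 3 * np.mean(ses)

    def test_empty_window_rejected(self):
        data = pd.DataFrame({"Q": [500.0, 1000.0, 1500.0], "A_net": [10.0, 15.0, 18.0]})
        with pytest.raises(ValueError, match=">= 3"):
            fit_r_light_kok(data)


class TestYin:
    def test_exact_line_recovers_intercept(self):
        Q = np.array([40.0, 60.0, 80.0, 100.0])
        phi = np.full_like(Q, 0.7)
        x = Q * phi / 4.0
        data = pd.DataFrame({"Q": Q, "phi_PSII": phi, "A_net": 0.45 * x - 0.8})
        res = fit_r_light_yin(data)
        assert res.R_light == pytest.approx(0.8, abs=1e-10)
        assert res.slope == pytest.approx(0.45, abs=1e-10)

    def test_missing_fluorescence_rejected(self):
        data = pd.DataFrame({"Q": [40.0, 60.0, 80.0], "A_net": [0.5, 1.5, 2.5]})
        with pytest.raises(ValueError, match="phi_PSII"):
            fit_r_light_yin(data)

    def test_zero_fluorescence_degenerate(self):
        data = pd.DataFrame({"Q": [40.0, 60.0, 80.0], "phi_PSII": [0.0, 0.0, 0.0],
                             "A_net": [0.5, 1.5, 2.5]})
        with pytest.raises(ValueError, match="degenerate"):
            fit_r_light_yin(data)


class TestWalkerOrt:
    @staticmethod
    def _lines(slopes, ci_star=40.0, r_light=1.1, n_ci=4):
        C_i = np.linspace(20.0, 150.0, n_ci)
        frames = [pd.DataFrame({"C_i": C_i, "A_net": s * (C_i - ci_star) - r_light, "Q": q})
                  for q, s in zip(100 + 50 * np.arange(len(slopes)), slopes)]
        return pd.concat(frames, ignore_index=True)

    def test_common_intersection_recovered_exactly(self):
        data = self._lines([0.02, 0.05, 0.09])
        res = fit_r_light_walker_ort(data)
        assert res.C_i_star == pytest.approx(40.0, abs=1e-9)
        assert res.R_light == pytest.approx(1.1, abs=1e-9)

    def test_two_lines_solvable_but_flagged(self):
        data = self._lines([0.02, 0.08])
        res = fit_r_light_walker_ort(data)
        assert res.C_i_star == pytest.approx(40.0, abs=1e-9)
        assert np.isnan(res.R_light_se)
        assert any("two" in w for w in res.warnings)

    def test_parallel_lines_rejected(self):
        data = self._lines([0.05, 0.05, 0.05])
        with pytest.raises(ValueError, match="parallel"):
            fit_r_light_walker_ort(data)


class TestVariableJ:
    def test_harley_equations_hand_arithmetic(self):
        # Gamma*=40, A=10, R_light=1, J_F=100 -> C_c = 40*188/56, then g_mc
        data = pd.DataFrame({"A_net": [10.0], "C_i": [250.0], "J_F": [100.0]})
        records, summary = fit_g_mc_variableJ(data, Gamma_star=40.0, R_light=1.0)
        assert records["C_c"].iloc[0] == pytest.approx(40.0 * 188.0 / 56.0)
        assert records["g_mc"].iloc[0] == pytest.approx(10.0 / (250.0 - 40.0 * 188.0 / 56.0))
        assert records["dCcdA"].iloc[0] == pytest.approx(12.0 * 40.0 * 100.0 / 56.0**2)
        assert bool(records["reliable"].iloc[0])  # 15.306 is inside [10, 50]

    def test_singular_record_flagged_invalid(self):
        # J_F = 4 (A + R_light): the Harley denominator collapses
        data = pd.DataFrame({"A_net": [10.0], "C_i": [250.0], "J_F": [44.0]})
        records, summary = fit_g_mc_variableJ(data, Gamma_star=40.0, R_light=1.0)
        assert not records["valid"].iloc[0]
        assert summary["n_valid"] == 0
        assert np.isnan(summary["g_mc_mean"])

    def test_reliability_window_boundaries_inclusive(self):
        # construct records with chosen dCcdA by inverting the Harley relations
        # with Gamma*=40 and the Harley denominator pinned at exactly 24, the
        # forward arithmetic 12*40*J/24^2 = J/1.2 is float-exact at the
        # boundary targets (J = 12 -> 10, J = 60 -> 50)
        targets = [5.0, 9.99, 10.0, 15.3, 25.0, 49.99, 50.0, 50.01, 60.0]
        G, RL, C_i = 40.0, 1.0, 3000.0
        rows = []
        for d in targets:
            J = d * 576.0 / 480.0
            x = (J - 24.0) / 4.0     # so J_F - 4(A + R_light) == 24 exactly
            rows.append({"A_net": x - RL, "C_i": C_i, "J_F": J})
        rows.append({"A_net": 10.0, "C_i": C_i, "J_F": 44.0})  # singular record
        records, summary = fit_g_mc_variableJ(pd.DataFrame(rows), Gamma_star=G, R_light=RL)
        assert records["dCcdA"].iloc[2] == 10.0 and records["dCcdA"].iloc[6] == 50.0
        np.testing.assert_allclose(records["dCcdA"].iloc[:-1], targets, rtol=1e-9)
        expected = [False, False, True, True, True, True, True, False, False, False]
        assert records["reliable"].tolist() == expected
        inside = records.loc[records["reliable"], "g_mc"]
        assert summary["n_reliable"] == 5
        assert summary["g_mc_mean"] == pytest.approx(inside.mean())

    def test_ci_below_cc_flagged_nonphysical(self):
        data = pd.DataFrame({"A_net": [10.0], "C_i": [100.0], "J_F": [100.0]})
        records, _ = fit_g_mc_variableJ(data, Gamma_star=40.0, R_light=1.0)
        assert not records["valid"].iloc[0]
        assert "non-physical" in records["flag"].iloc[0]

    def test_jf_from_fluorescence_calibration(self, make_curve):
        data = make_curve("gmc_variableJ").drop(columns=["J_F"])
        records, summary = fit_g_mc_variableJ(data, Gamma_star=42.75, R_light=1.0, calib=0.42)
        assert summary["g_mc_mean"] == pytest.approx(0.25, rel=1e-6)

    def test_missing_calibration_rejected(self):
        data = pd.DataFrame({"A_net": [10.0], "C_i": [250.0],
                             "Q": [1500.0], "phi_PSII": [0.2]})
        with pytest.raises(ValueError, match="calib"):
            fit_g_mc_variableJ(data, Gamma_star=40.0, R_light=1.0)

    def test_noiseless_generator_round_trip(self, make_curve):
        data = make_curve("gmc_variableJ")
        records, summary = fit_g_mc_variableJ(data, Gamma_star=42.75, R_light=1.0)
        np.testing.assert_allclose(records["g_mc"], 0.25, rtol=1e-9)
        assert summary["g_mc_mean"] == pytest.approx(0.25, rel=1e-9)
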
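"""Photosynthetic light-response (A-Q) and CO2-response (A-Ci) curve fitting.

The light response is the non-rectangular hyperbola: gross assimilation is
the lower root of

    theta_J * Ag^2 - (phi_J Q + A_sat) Ag + phi_J Q A_sat = 0,

minus dark respiration R_d.  phi_J is the apparent quantum yield
(mol CO2 mol-1 photons), theta_J the empirical curvature in (0, 1], A_sat
the light-saturated gross rate.

The CO2 response is the Farquhar-von Caemmerer-Berry (FvCB) C3 model on the
intercellular-CO2 (Ci) basis: net assimilation is the minimum of the
Rubisco-limited (A_c), RuBP-regeneration-limited (A_j) and triose-phosphate-
utilisation-limited (A_p) rates, less R_d:

    A_c = V_cmax (Ci - Gamma*) / (Ci + K_m),    K_m = K_c (1 + O / K_o)
    A_j = J (Ci - Gamma*) / (4 Ci + 8 Gamma*)
    A_p = 3 V_TPU

Fitting estimates (V_cmax, J_max, R_d) — and V_TPU when the high-CO2 end of
the curve flattens — by direct nonlinear least squares on the min rule, with
looped starting values.  Kinetic constants (Gamma*, K_c, K_o) are
temperature-adjusted to the curve's mean leaf temperature before fitting.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .constants import BERNACCHI_KINETICS, O2_DEFAULT, T_REF
from .fitting import FitResult, fit_multistart, start_grid
from .temp_response import eval_t_response

__all__ = [
    "eval_aq",
    "fit_aq_response",
    "eval_fvcb_ci",
    "fit_aci_response",
    "kinetics_at_temperature",
]


def eval_aq(params: Mapping[str, float], Q) -> np.ndarray | float:
    """Net assimilation from the non-rectangular hyperbola light response.

    ``params`` needs A_sat, phi_J, theta_J, R_d.  At theta_J = 0 the form
    degenerates to the rectangular hyperbola, handled analytically.
    """
    Q = np.asarray(Q, dtype=float)
    scalar = Q.ndim == 0
    Q = np.atleast_1d(Q)
    if np.any(Q < 0):
        raise ValueError("Q (PPFD) must be non-negative")
    A_sat, phi, theta, R_d = (params["A_sat"], params["phi_J"],
                              params["theta_J"], params["R_d"])
    s = phi * Q + A_sat
    if theta == 0.0:
        with np.errstate(divide="ignore", invalid="ignore"):
            gross = np.where(s > 0, phi * Q * A_sat / s, 0.0)
    else:
        disc = np.clip(s**2 - 4.0 * theta * phi * Q * A_sat, 0.0, None)
        gross = (s - np.sqrt(disc)) / (2.0 * theta)
    A = gross - R_d
    return float(A[0]) if scalar else A


def fit_aq_response(
    data: pd.DataFrame,
    *,
    n_starts_axis: int = 3,
) -> FitResult:
    """Fit the A-Q non-rectangular hyperbola to (A_net, Q) observations.

    Requires >= 6 observations spanning sub-saturating and saturating light.
    Returns estimates and standard errors for (A_sat, phi_J, theta_J, R_d),
    plus a plot of the data, fitted line and a +/-SE band.
    """
    Q = np.asarray(data["Q"], dtype=float)
    A = np.asarray(data["A_net"], dtype=float)
    keep = np.isfinite(Q) & np.isfinite(A)
    Q, A = Q[keep], A[keep]
    if Q.size < 6:
        raise ValueError(f"fit_aq_response needs >= 6 observations, got {Q.size}")

    # moment-based starting guesses
    order = np.argsort(Q)
    Qs, As = Q[order], A[order]
    Rd0 = max(-As[0], 0.1) if Qs[0] <= 1 else 0.5
    Asat0 = float(As.max() + Rd0)
    low = Qs > 0
    phi0 = float(np.clip((As[low][0] + Rd0) / Qs[low][0], 1e-3, 0.12)) if low.any() else 0.05
    mult = np.geomspace(0.5, 2.0, n_starts_axis)
    starts = start_grid(
        {"A_sat": Asat0, "phi_J": phi0, "theta_J": 0.7, "R_d": Rd0},
        {"phi_J": tuple(mult), "theta_J": (0.4 / 0.7, 1.0, 0.99 / 0.7), "R_d": tuple(mult)},
    )
    bounds = {"A_sat": (1e-6, np.inf), "phi_J": (1e-6, 0.5),
              "theta_J": (1e-6, 1.0), "R_d": (-10.0, 50.0)}

    def predict(p):
        return np.asarray(eval_aq(p, Q))

    res = fit_multistart("aq", predict, A, starts, bounds)
    if res.success and np.ptp(Q[Q > 0]) > 0:
        # all-saturating designs cannot pin down the initial slope
        if Q[Q > 0].min() > 0.5 * res.params["A_sat"] / max(res.params["phi_J"], 1e-9):
            res.warnings.append("no sub-saturating light levels; phi_J unidentifiable")
    res.extra["data"] = {"Q": Q.tolist(), "A_net": A.tolist()}
    res._plot_fn = _aq_plot_fn(Q, A)
    return res


def _aq_plot_fn(Q, A):
    def plot(result: FitResult):
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        Qg = np.linspace(0.0, max(Q.max(), 1.0), 300)
        if result.success:
            Ag = np.asarray(eval_aq(result.params, Qg))
            # pointwise SE band via parameter-gradient propagation
            band = _aq_se_band(result, Qg)
            ax.fill_between(Qg, Ag - band, Ag + band, color="0.8", label="fit +/- SE")
            ax.plot(Qg, Ag, "b-", label="fit")
        ax.plot(Q, A, "ko", label="data")
        ax.set_xlabel("Q (umol m$^{-2}$ s$^{-1}$)")
        ax.set_ylabel("A_net (umol m$^{-2}$ s$^{-1}$)")
        ax.legend(frameon=False)
        fig.tight_layout()
        return fig

    return plot


def _aq_se_band(result: FitResult, Qg: np.ndarray) -> np.ndarray:
    names = list(result.params)
    p0 = result.params
    f0 = np.asarray(eval_aq(p0, Qg))
    var = np.zeros_like(Qg)
    for nm in names:
        h = max(abs(p0[nm]) * 1e-6, 1e-9)
        p1 = dict(p0)
        p1[nm] = p0[nm] + h
        grad = (np.asarray(eval_aq(p1, Qg)) - f0) / h
        var = var + (grad * result.se.get(nm, 0.0)) ** 2
    return np.sqrt(var)


def kinetics_at_temperature(T_leaf: float, kinetics: Mapping[str, float] | None = None) -> dict[str, float]:
    """Arrhenius-scale Gamma*, K_c, K_o from 25 degC to ``T_leaf`` (K).

    ``kinetics`` may override any of the 25 degC values or activation
    energies; defaults are the Bernacchi tobacco set.  Returns Gamma_star,
    K_c (umol mol-1), K_o (mmol mol-1) at T_leaf.
    """
    kin = dict(BERNACCHI_KINETICS)
    if kinetics:
        kin.update(kinetics)
    out = {}
    for name in ("Gamma_star", "K_c", "K_o"):
        out[name] = float(eval_t_response(
            "arrhenius",
            {"k_ref": kin[f"{name}25"], "E_a": kin[f"{name}_Ea"], "T_ref": T_REF},
            T_leaf,
        ))
    return out


def eval_fvcb_ci(params: Mapping[str, float], C_i) -> pd.DataFrame:
    """FvCB limitation rates on the Ci basis.

    ``params``: V_cmax, J (realised electron transport, or J_max at
    saturating light), V_TPU, R_d, Gamma_star, K_c (umol mol-1),
    K_o (mmol mol-1), O (mmol mol-1, default 210).

    Returns a DataFrame with columns C_i, A_c, A_j, A_p, A_mod and the
    limitation label of the realised minimum.
    """
    C_i = np.atleast_1d(np.asarray(C_i, dtype=float))
    if np.any(C_i <= 0):
        raise ValueError("C_i must be positive")
    V_cmax = params["V_cmax"]
    J = params.get("J", params.get("J_max"))
    if J is None:
        raise ValueError("params must provide J or J_max")
    V_TPU = params.get("V_TPU", np.inf)
    R_d = params.get("R_d", 0.0)
    G = params["Gamma_star"]
    K_m = params.get("K_m")
    if K_m is None:
        O = params.get("O", O2_DEFAULT)
        K_m = params["K_c"] * (1.0 + O / params["K_o"])
    A_c = V_cmax * (C_i - G) / (C_i + K_m)
    A_j = J * (C_i - G) / (4.0 * C_i + 8.0 * G)
    A_p = np.full_like(C_i, 3.0 * V_TPU)
    stacked = np.vstack([A_c, A_j, A_p])
    idx = np.argmin(stacked, axis=0)
    A_mod = stacked[idx, np.arange(C_i.size)] - R_d
    label = np.array(["Ac", "Aj", "Ap"])[idx]
    return pd.DataFrame({
        "C_i": C_i, "A_c": A_c, "A_j": A_j, "A_p": A_p,
        "A_mod": A_mod, "limitation": label,
    })


def _tpu_flattening(C_i: np.ndarray, A: np.ndarray, slope_tol: float = 0.01) -> bool:
    """High-CO2 flattening heuristic: slope of the last 3 points < tol."""
    order = np.argsort(C_i)
    c, a = C_i[order][-3:], A[order][-3:]
    if np.ptp(c) <= 0:
        return False
    slope = np.polyfit(c, a, 1)[0]
    return slope < slope_tol


def fit_aci_response(
    data: pd.DataFrame,
    kinetics: Mapping[str, float] | None = None,
    *,
    fit_tpu: bool | None = None,
    per_point_temperature: bool = False,
    use_grid_search: bool = False,
) -> FitResult:
    """Fit the FvCB model to an A-Ci curve.

    Parameters
    ----------
    data
        Canonical table with A_net and C_i (T_leaf optional; 25 degC assumed
        when absent, with a warning).
    kinetics
        Overrides for the 25 degC kinetic constants / activation energies,
        plus optionally fixed ``g_mc`` (Ci is then converted to a
        chloroplastic basis via C_c = C_i - A/g_mc before fitting).
    fit_tpu
        Force TPU limitation on/off; default ``None`` applies the
        high-CO2-flattening heuristic.
    per_point_temperature
        Adjust kinetics per observation instead of at the mean T_leaf.
    use_grid_search
        Also run a coarse grid search over (V_cmax, J_max, R_d) and keep the
        better of grid-refined and default multistart solutions.
    """
    C_i = np.asarray(data["C_i"], dtype=float)
    A = np.asarray(data["A_net"], dtype=float)
    keep = np.isfinite(C_i) & np.isfinite(A)
    C_i, A = C_i[keep], A[keep]
    if C_i.size < 5:
        raise ValueError(f"fit_aci_response needs >= 5 observations, got {C_i.size}")
    kinetics = dict(kinetics or {})
    g_mc = kinetics.pop("g_mc", None)
    if "T_leaf" in data:
        T = np.asarray(data["T_leaf"], dtype=float)[keep]
    else:
        T = np.full_like(C_i, T_REF)

    C_basis = C_i - A / g_mc if g_mc is not None else C_i

    if per_point_temperature:
        kin_rows = [kinetics_at_temperature(t, kinetics) for t in T]
        G = np.array([r["Gamma_star"] for r in kin_rows])
        K_c = np.array([r["K_c"] for r in kin_rows])
        K_o = np.array([r["K_o"] for r in kin_rows])
    else:
        kin = kinetics_at_temperature(float(np.mean(T)), kinetics)
        G, K_c, K_o = kin["Gamma_star"], kin["K_c"], kin["K_o"]
    O = kinetics.get("O", O2_DEFAULT)
    K_m = K_c * (1.0 + O / K_o)

    do_tpu = _tpu_flattening(C_basis, A) if fit_tpu is None else bool(fit_tpu)

    def predict(p):
        A_c = p["V_cmax"] * (C_basis - G) / (C_basis + K_m)
        A_j = p["J_max"] * (C_basis - G) / (4.0 * C_basis + 8.0 * G)
        A_mod = np.minimum(A_c, A_j)
        if do_tpu:
            A_mod = np.minimum(A_mod, 3.0 * p["V_TPU"])
        return A_mod - p["R_d"]

    # starting guesses: Rubisco slope from low-Ci points, J from the top
    order = np.argsort(C_basis)
    c_lo, a_lo = C_basis[order][:3], A[order][:3]
    a_hi = A[order][-3:].mean()
    Gm = float(np.mean(G))
    Km_m = float(np.mean(K_m))
    with np.errstate(all="ignore"):
        V0 = float(np.clip(np.median(a_lo * (c_lo + Km_m) / np.clip(c_lo - Gm, 1.0, None)),
                           5.0, 500.0))
    J0 = float(np.clip(4.4 * a_hi, 10.0, 800.0))
    base = {"V_cmax": V0, "J_max": J0, "R_d": 1.0}
    spreads = {"V_cmax": (0.7, 1.0, 1.4), "J_max": (0.7, 1.0, 1.4)}
    bounds = {"V_cmax": (1e-3, 1e3), "J_max": (1e-3, 2e3),
              "R_d": (-10.0, 50.0), "V_TPU": (1e-3, 200.0)}
    if do_tpu:
        base["V_TPU"] = float(max((a_hi + base["R_d"]) / 3.0, 1.0))
    starts = start_grid(base, spreads)
    if use_grid_search:
        starts = starts + _coarse_grid_starts(base, do_tpu)
    res = fit_multistart("fvcb_ci", predict, A, starts, bounds)

    if res.success:
        p = dict(res.params)
        if not do_tpu:
            p["V_TPU"] = np.inf
        modelled = eval_fvcb_ci(
            {**p, "J": p["J_max"], "Gamma_star": Gm, "K_m": Km_m}, C_basis)
        res.extra["modelled"] = modelled
        res.extra["kinetics"] = {"Gamma_star": Gm, "K_c": float(np.mean(K_c)),
                                 "K_o": float(np.mean(K_o)), "K_m": Km_m, "O": O,
                                 "T_leaf_mean": float(np.mean(T))}
        res.extra["tpu_fitted"] = do_tpu
        lims = set(modelled["limitation"])
        if "Aj" not in lims:
            res.warnings.append("A_j never limiting over the data range; J_max unidentifiable")
        if "Ac" not in lims:
            res.warnings.append("A_c never limiting over the data range; V_cmax unidentifiable")
        res._plot_fn = _aci_plot_fn(C_basis, A, p, Gm, Km_m)
    else:
        i = int(np.argmax(np.abs(A - np.median(A))))
        res.message += f"; largest-deviation point: C_i={C_i[i]:.1f}, A={A[i]:.2f}"
    return res


def _coarse_grid_starts(base: Mapping[str, float], do_tpu: bool) -> list[dict]:
    vs = np.linspace(0.4, 2.0, 6)
    starts = []
    for fv in vs:
        for fj in vs:
            s = {"V_cmax": base["V_cmax"] * fv, "J_max": base["J_max"] * fj, "R_d": 1.0}
            if do_tpu:
                s["V_TPU"] = base["V_TPU"]
            starts.append(s)
    return starts


def _aci_plot_fn(C_i, A, params, Gamma_star, K_m):
    def plot(result: FitResult):
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        cg = np.linspace(max(C_i.min(), Gamma_star * 0.5), C_i.max(), 300)
        m = eval_fvcb_ci({**params, "J": params["J_max"], "Gamma_star": Gamma_star,
                          "K_m": K_m}, cg)
        ax.plot(cg, m["A_c"] - params["R_d"], color="tab:blue", lw=1, label="A_c")
        ax.plot(cg, m["A_j"] - params["R_d"], color="tab:orange", lw=1, label="A_j")
        if np.isfinite(params.get("V_TPU", np.inf)):
            ax.axhline(3 * params["V_TPU"] - params["R_d"], color="tab:green", lw=1, label="A_p")
        ax.plot(cg, m["A_mod"], "k-", lw=2, label="A_mod")
        ax.plot(C_i, A, "o", mfc="white", mec="k", label="data")
        ax.set_xlabel("C_i (umol mol$^{-1}$)")
        ax.set_ylabel("A_net (umol m$^{-2}$ s$^{-1}$)")
        ax.set_ylim(bottom=min(-2.0, float(np.min(A)) - 1.0))
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        return fig

    return plot
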
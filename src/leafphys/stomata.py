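"""Empirical stomatal-conductance models: Ball-Berry, Leuning, Medlyn.

All three express stomatal conductance to water vapour g_sw
(mol m-2 s-1) as a baseline g0 plus a term proportional to assimilation
scaled by a humidity/CO2 index:

    ballberry: g_sw = g0 + g1 * A_net * RH / C_s
    leuning:   g_sw = g0 + g1 * A_net / [(C_s - Gamma)(1 + D/D0)]
    medlyn:    g_sw = g0 + 1.6 (1 + g1/sqrt(D)) A_net / C_s

RH is a fraction in [0, 1]; D is leaf-to-air vapour pressure deficit (kPa);
C_s leaf-surface CO2 (umol mol-1); Gamma a CO2 compensation point
(umol mol-1, fixed, not estimated).  The Medlyn model is the common
explicit approximation of the optimal-stomata result, with g1 in kPa^0.5.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .fitting import FitResult, fit_multistart, start_grid

__all__ = ["GS_MODELS", "eval_gs_model", "fit_gs_models"]

GS_MODELS = ("ballberry", "leuning", "medlyn")

_PARAMS = {"ballberry": ("g0", "g1"), "leuning": ("g0", "g1", "D0"), "medlyn": ("g0", "g1")}


def eval_gs_model(model_id: str, params: Mapping[str, float], drivers: Mapping) -> np.ndarray | float:
    """Evaluate a stomatal model for driver arrays (A_net, C_s, RH, D)."""
    A = np.asarray(drivers["A_net"], dtype=float)
    scalar = A.ndim == 0
    A = np.atleast_1d(A)
    C_s = np.atleast_1d(np.asarray(drivers["C_s"], dtype=float))
    g0 = params["g0"]
    if np.any(C_s <= 0):
        raise ValueError("C_s must be positive")
    if model_id == "ballberry":
        RH = np.atleast_1d(np.asarray(drivers["RH"], dtype=float))
        if np.any((RH < 0) | (RH > 1)):
            raise ValueError("RH must be a fraction in [0, 1]")
        g = g0 + params["g1"] * A * RH / C_s
    elif model_id == "leuning":
        D = np.atleast_1d(np.asarray(drivers["D"], dtype=float))
        if np.any(D <= 0):
            raise ValueError("D must be positive (kPa)")
        Gamma = params.get("Gamma", 0.0)
        if np.any(np.abs(C_s - Gamma) < 1e-9):
            raise ValueError("C_s equals Gamma: Leuning denominator is singular")
        g = g0 + params["g1"] * A / ((C_s - Gamma) * (1.0 + D / params["D0"]))
    elif model_id == "medlyn":
        D = np.atleast_1d(np.asarray(drivers["D"], dtype=float))
        if np.any(D <= 0):
            raise ValueError("D must be positive (kPa)")
        g = g0 + 1.6 * (1.0 + params["g1"] / np.sqrt(D)) * A / C_s
    else:
        raise ValueError(f"unknown stomatal model {model_id!r}; choose from {GS_MODELS}")
    return float(g[0]) if scalar else g


def fit_gs_models(
    data: pd.DataFrame,
    models: Iterable[str] = GS_MODELS,
    *,
    Gamma: float = 50.0,
) -> dict[str, FitResult]:
    """Fit the requested stomatal models to observed g_sw and drivers.

    ``Gamma`` (Leuning only) is held fixed to preserve identifiability.
    Returns model_id -> FitResult with parameters, SEs, SSR/AIC and an
    observed-vs-fitted plot.
    """
    models = list(models)
    unknown = [m for m in models if m not in GS_MODELS]
    if unknown:
        raise ValueError(f"unknown model(s): {unknown}; choose from {GS_MODELS}")
    need = {"g_sw", "A_net", "C_s"}
    if "ballberry" in models:
        need.add("RH")
    if {"leuning", "medlyn"} & set(models):
        need.add("D")
    missing = sorted(need - set(data.columns))
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    sub = data.dropna(subset=sorted(need))
    g_obs = np.asarray(sub["g_sw"], dtype=float)
    drivers = {c: np.asarray(sub[c], dtype=float) for c in need if c != "g_sw"}

    out: dict[str, FitResult] = {}
    for m in models:
        k = len(_PARAMS[m])
        if g_obs.size < k + 2:
            raise ValueError(f"{m}: need >= {k + 2} observations, got {g_obs.size}")
        g0_0 = float(max(g_obs.min() * 0.5, 1e-3))
        base = {"g0": g0_0}
        spreads = {"g1": (0.3, 1.0, 3.0)}
        if m == "ballberry":
            base["g1"] = 9.0
        elif m == "medlyn":
            base["g1"] = 4.0
        else:
            base.update({"g1": max(float(np.median(
                (g_obs - g0_0) * (drivers["C_s"] - Gamma) * 2.0 / np.clip(drivers["A_net"], 0.1, None))), 0.5),
                "D0": 1.5})
            spreads["D0"] = (0.3, 1.0, 3.0)
        starts = start_grid(base, spreads)
        bounds = {"g0": (0.0, 10.0), "g1": (1e-6, 1e3), "D0": (1e-3, 50.0)}

        def predict(p, m=m):
            pp = dict(p)
            if m == "leuning":
                pp["Gamma"] = Gamma
            return np.asarray(eval_gs_model(m, pp, drivers))

        res = fit_multistart(m, predict, g_obs, starts, bounds)
        if m == "leuning":
            res.extra["Gamma_fixed"] = Gamma
        if res.success:
            A = drivers["A_net"]
            if np.allclose(A, 0.0):
                res.warnings.append("A_net is identically zero; g1 unidentifiable")
            if m == "ballberry" and np.ptp(drivers["RH"]) < 1e-9 and np.ptp(drivers["C_s"]) < 1e-9:
                res.warnings.append("constant RH and C_s: Ball-Berry slope term degenerate "
                                    "with any conductance offset")
            res._plot_fn = _gs_plot_fn(g_obs)
        out[m] = res
    return out


def _gs_plot_fn(g_obs):
    def plot(result: FitResult):
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.plot(result.fitted, g_obs, "ko")
        lim = [min(g_obs.min(), result.fitted.min()), max(g_obs.max(), result.fitted.max())]
        ax.plot(lim, lim, "b--", lw=1, label="1:1")
        ax.set_xlabel("fitted g_sw (mol m$^{-2}$ s$^{-1}$)")
        ax.set_ylabel("observed g_sw (mol m$^{-2}$ s$^{-1}$)")
        ax.set_title(result.model)
        ax.legend(frameon=False)
        fig.tight_layout()
        return fig

    return plot
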
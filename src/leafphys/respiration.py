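"""Light respiration (Kok, Yin, Walker-Ort) and variable-J mesophyll conductance.

Respiration in the light (R_light) cannot be measured directly; the three
classical estimators all exploit linear regions of gas-exchange responses:

* **Kok**: A_net is regressed on irradiance Q inside a low-light window
  (default 40-100 umol m-2 s-1, below the Kok-effect break);
  R_light = -intercept.
* **Yin**: A_net is regressed on Q * phi_PSII / 4 (fluorescence-corrected
  light use), removing the bias from declining photochemical yield;
  R_light = -intercept, the slope being a lumped calibration factor.
* **Walker-Ort**: A-Ci slopes and intercepts measured at several
  irradiances intersect at a common point (Ci*, -R_light); regressing
  intercepts on slopes gives both the apparent photocompensation point
  Ci* (= -slope of that regression) and R_light (= -intercept).

The variable-J method (Harley et al. 1992) combines gas exchange with the
fluorescence-based electron transport rate J_F to estimate chloroplastic
CO2 and mesophyll conductance per observation:

    C_c   = Gamma* [J_F + 8 (A + R_light)] / [J_F - 4 (A + R_light)]
    g_mc  = A / (C_i - C_c)
    dCc/dA = 12 Gamma* J_F / [J_F - 4 (A + R_light)]^2

Records with dCc/dA between 10 and 50 (inclusive) are flagged reliable, and
the summary g_mc is the mean over reliable records only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RLightFit",
    "fit_r_light_kok",
    "fit_r_light_yin",
    "fit_r_light_walker_ort",
    "fit_g_mc_variableJ",
]

#: Inclusive reliability window on dCc/dA for variable-J g_mc estimates.
RELIABILITY_BOUNDS = (10.0, 50.0)


@dataclass
class RLightFit:
    """Light-respiration estimate from one of the three linear methods."""
    method: str
    R_light: float                 # positive magnitude, umol m-2 s-1
    R_light_se: float
    slope: float
    slope_se: float
    C_i_star: float | None = None  # Walker-Ort only, umol mol-1
    C_i_star_se: float | None = None
    n_obs: int = 0
    warnings: list[str] = field(default_factory=list)
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("method", "R_light", "R_light_se", "slope", "slope_se",
              "C_i_star", "C_i_star_se", "n_obs", "warnings")}
        return d


def _ols(x: np.ndarray, y: np.ndarray):
    X = sm.add_constant(np.asarray(x, dtype=float))
    return sm.OLS(np.asarray(y, dtype=float), X).fit()


def fit_r_light_kok(
    data: pd.DataFrame,
    Q_bounds: tuple[float, float] = (40.0, 100.0),
) -> RLightFit:
    """Kok method: OLS of A_net on Q inside the low-light window.

    Sign convention: R_light is reported as a positive magnitude (the CO2
    efflux); the fitted intercept is -R_light.
    """
    lo, hi = Q_bounds
    sub = data[(data["Q"] >= lo) & (data["Q"] <= hi)].dropna(subset=["A_net", "Q"])
    if len(sub) < 3:
        raise ValueError(
            f"Kok method needs >= 3 observations with Q in [{lo:g}, {hi:g}]; got {len(sub)}")
    res = _ols(sub["Q"], sub["A_net"])
    return RLightFit(
        method="kok",
        R_light=float(-res.params[0]), R_light_se=float(res.bse[0]),
        slope=float(res.params[1]), slope_se=float(res.bse[1]),
        n_obs=len(sub), details={"Q_bounds": [lo, hi]},
    )


def fit_r_light_yin(
    data: pd.DataFrame,
    Q_bounds: tuple[float, float] = (40.0, 100.0),
) -> RLightFit:
    """Yin method: OLS of A_net on Q*phi_PSII/4 inside the low-light window."""
    if "phi_PSII" not in data:
        raise ValueError("Yin method requires a phi_PSII column")
    lo, hi = Q_bounds
    sub = data[(data["Q"] >= lo) & (data["Q"] <= hi)].dropna(subset=["A_net", "Q", "phi_PSII"])
    if len(sub) < 3:
        raise ValueError(
            f"Yin method needs >= 3 observations with Q in [{lo:g}, {hi:g}]; got {len(sub)}")
    x = np.asarray(sub["Q"], dtype=float) * np.asarray(sub["phi_PSII"], dtype=float) / 4.0
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate regressor: Q*phi_PSII/4 has no variation")
    res = _ols(x, sub["A_net"])
    return RLightFit(
        method="yin",
        R_light=float(-res.params[0]), R_light_se=float(res.bse[0]),
        slope=float(res.params[1]), slope_se=float(res.bse[1]),
        n_obs=len(sub), details={"Q_bounds": [lo, hi]},
    )


def fit_r_light_walker_ort(
    data: pd.DataFrame,
    low_Ci_window: tuple[float, float] = (0.0, 300.0),
    Q_col: str = "Q",
) -> RLightFit:
    """Walker-Ort method: common intersection of low-Ci A-Ci lines.

    Per irradiance level, A_net is regressed on C_i within the low-Ci
    window; the per-level (slope_i, intercept_i) pairs are then regressed as
    intercept_i = -R_light - C_i_star * slope_i.
    """
    lo, hi = low_Ci_window
    sub = data[(data["C_i"] >= lo) & (data["C_i"] <= hi)].dropna(subset=["A_net", "C_i", Q_col])
    levels = sorted(sub[Q_col].unique())
    if len(levels) < 2:
        raise ValueError(f"Walker-Ort needs >= 2 irradiance levels; got {len(levels)}")
    slopes, intercepts = [], []
    for q in levels:
        grp = sub[sub[Q_col] == q]
        if len(grp) < 3:
            raise ValueError(
                f"Walker-Ort needs >= 3 low-Ci observations per irradiance; "
                f"Q={q:g} has {len(grp)}")
        res = _ols(grp["C_i"], grp["A_net"])
        intercepts.append(float(res.params[0]))
        slopes.append(float(res.params[1]))
    slopes_a, intercepts_a = np.asarray(slopes), np.asarray(intercepts)
    if np.ptp(slopes_a) < 1e-10:
        raise ValueError("A-Ci slopes indistinguishable across irradiances (parallel lines); "
                         "the intercept-on-slope regression is collinear")
    warnings_ = []
    if len(levels) == 2:
        # two-point regression: exact solution, no residual dof for SEs
        b1 = (intercepts_a[1] - intercepts_a[0]) / (slopes_a[1] - slopes_a[0])
        b0 = intercepts_a[0] - b1 * slopes_a[0]
        se0 = se1 = float("nan")
        warnings_.append("only two irradiance levels: SEs undefined")
    else:
        res2 = _ols(slopes_a, intercepts_a)
        b0, b1 = float(res2.params[0]), float(res2.params[1])
        se0, se1 = float(res2.bse[0]), float(res2.bse[1])
    return RLightFit(
        method="walker_ort",
        R_light=float(-b0), R_light_se=se0,
        slope=float(b1), slope_se=se1,
        C_i_star=float(-b1), C_i_star_se=se1,
        n_obs=int(len(sub)), warnings=warnings_,
        details={"slopes": slopes, "intercepts": intercepts,
                 "low_Ci_window": [lo, hi], "Q_levels": [float(q) for q in levels]},
    )


def fit_g_mc_variableJ(
    data: pd.DataFrame,
    Gamma_star: float,
    R_light: float,
    *,
    J_F_col: str = "J_F",
    calib: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Variable-J mesophyll conductance with reliability screening.

    Parameters
    ----------
    data
        Canonical table with A_net, C_i and either a measured electron
        transport column (``J_F_col``) or phi_PSII + Q plus ``calib``.
    Gamma_star
        Photorespiratory CO2 compensation point (umol mol-1) at the
        measurement temperature.
    R_light
        Light respiration (positive magnitude, umol m-2 s-1), e.g. from one
        of the fit_r_light_* estimators.
    calib
        Lumped fluorescence calibration (leaf absorptance x PSII fraction)
        for computing J_F = calib * Q * phi_PSII when no measured column is
        present.  There is no default: it must be measured or supplied.

    Returns
    -------
    (records, summary): per-observation DataFrame with C_c, g_mc, dCcdA,
    ``reliable`` (10 <= dCcdA <= 50, inclusive) and ``valid`` flags, plus a
    summary dict whose ``g_mc_mean`` averages reliable records only.
    """
    A = np.asarray(data["A_net"], dtype=float)
    C_i = np.asarray(data["C_i"], dtype=float)
    if J_F_col in data:
        J_F = np.asarray(data[J_F_col], dtype=float)
    else:
        if calib is None:
            raise ValueError(
                f"no {J_F_col!r} column; supply calib to compute J_F = calib*Q*phi_PSII")
        if "phi_PSII" not in data or "Q" not in data:
            raise ValueError("computing J_F requires phi_PSII and Q columns")
        J_F = calib * np.asarray(data["Q"], dtype=float) * np.asarray(data["phi_PSII"], dtype=float)

    x = A + R_light
    denom = J_F - 4.0 * x
    valid = denom > 1e-9
    reason = np.where(valid, "", "J_F <= 4(A_net + R_light): electron transport "
                                 "insufficient; C_c undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        C_c = np.where(valid, Gamma_star * (J_F + 8.0 * x) / denom, np.nan)
        dCcdA = np.where(valid, 12.0 * Gamma_star * J_F / denom**2, np.nan)
        g_mc = np.where(valid & (C_i > C_c), A / (C_i - C_c), np.nan)
    nonphys = valid & ~(C_i > C_c)
    reason = np.where(nonphys, "C_i <= C_c: non-physical gradient", reason)
    lo, hi = RELIABILITY_BOUNDS
    reliable = valid & ~nonphys & (dCcdA >= lo) & (dCcdA <= hi)

    records = pd.DataFrame({
        "A_net": A, "C_i": C_i, "J_F": J_F,
        "C_c": C_c, "g_mc": g_mc, "dCcdA": dCcdA,
        "valid": valid & ~nonphys, "reliable": reliable, "flag": reason,
    })
    g_rel = records.loc[records["reliable"], "g_mc"]
    n_rel = int(reliable.sum())
    summary = {
        "Gamma_star": float(Gamma_star),
        "R_light": float(R_light),
        "n_records": int(len(records)),
        "n_valid": int(records["valid"].sum()),
        "n_reliable": n_rel,
        "g_mc_mean": float(g_rel.mean()) if n_rel else float("nan"),
        "g_mc_se": float(g_rel.std(ddof=1) / np.sqrt(n_rel)) if n_rel > 1 else float("nan"),
        "reliability_bounds": list(RELIABILITY_BOUNDS),
    }
    return records, summary


def plot_gmc_reliability(records: pd.DataFrame):
    """Scatter of g_mc against dCc/dA with the reliability window shaded."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    lo, hi = RELIABILITY_BOUNDS
    ax.axvspan(lo, hi, color="0.9", label="reliable window")
    ok = records["reliable"]
    ax.plot(records.loc[~ok, "dCcdA"], records.loc[~ok, "g_mc"], "o", mfc="white",
            mec="k", label="unreliable")
    ax.plot(records.loc[ok, "dCcdA"], records.loc[ok, "g_mc"], "ko", label="reliable")
    ax.set_xlabel(r"$\delta C_c / \delta A$")
    ax.set_ylabel("g_mc (mol m$^{-2}$ s$^{-1}$)")
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig
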
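"""Hydraulic vulnerability curves and leaf pressure-volume analysis.

**Vulnerability curves** relate percent loss of conductivity (PLC, %) to
xylem water potential psi (MPa, <= 0 internally; positive tensions are
auto-negated with a notice).  Two forms are fitted:

    sigmoidal: PLC = 100 / (1 + exp(a (psi - b)))        b = P50, a > 0
    weibull:   PLC = 100 (1 - exp(-(tension/b_w)^c_w))   tension = -psi

Derived thresholds use the sigmoidal tangent convention: air entry
P_e = b + 2/a, hydraulic failure P_max = b - 2/a.

**Pressure-volume curves** relate leaf water potential to relative water
content (RWC, %) during dehydration.  After turgor loss, 1/|psi| is linear
in (100 - RWC); the fitted line gives the osmotic potential at full turgor
pi_o (its extrapolated intercept), the osmotic line pi(RWC), turgor
P = psi - pi, the turgor loss point (first P = 0 crossing) and the relative
capacitance at full turgor C_ft (slope of RWC fraction vs psi before TLP,
MPa-1).
"""

from __future__ import annotations

import warnings as _warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .fitting import FitResult, fit_multistart, start_grid

__all__ = ["eval_vuln", "fit_hydra_vuln_curve", "fit_pv_curve"]


def eval_vuln(model_id: str, params: Mapping[str, float], psi) -> np.ndarray | float:
    """Predicted PLC (%) at water potential(s) psi (MPa, <= 0)."""
    psi_arr = np.asarray(psi, dtype=float)
    scalar = psi_arr.ndim == 0
    psi_arr = np.atleast_1d(psi_arr)
    if model_id == "sigmoidal":
        z = np.clip(params["a"] * (psi_arr - params["b"]), -700, 700)
        plc = 100.0 / (1.0 + np.exp(z))
    elif model_id == "weibull":
        tension = np.clip(-psi_arr, 0.0, None)
        plc = 100.0 * (1.0 - np.exp(-((tension / params["b_w"]) ** params["c_w"])))
    else:
        raise ValueError(f"unknown vulnerability model {model_id!r}")
    return float(plc[0]) if scalar else plc


def _normalize_psi(psi: np.ndarray, context: str) -> np.ndarray:
    """Internal sign convention: water potential <= 0 MPa."""
    if np.nanmedian(psi) > 0:
        _warnings.warn(f"{context}: psi given as positive tension; negating to MPa <= 0",
                       stacklevel=3)
        return -psi
    return psi


def fit_hydra_vuln_curve(data: pd.DataFrame) -> dict[str, FitResult]:
    """Fit sigmoidal and Weibull models to (psi, PLC) data.

    Returns both fits with derived P_e / P_50 / P_max (sigmoidal) and the
    tension at 50% loss (weibull).  Non-convergence of one model does not
    block the other.
    """
    sub = data.dropna(subset=["psi", "PLC"])
    psi = _normalize_psi(np.asarray(sub["psi"], dtype=float), "fit_hydra_vuln_curve")
    plc = np.asarray(sub["PLC"], dtype=float)
    if psi.size < 5:
        raise ValueError(f"need >= 5 observations, got {psi.size}")
    if np.any((plc < 0) | (plc > 100)):
        raise ValueError("PLC must lie in [0, 100]")
    if np.ptp(plc) < 1e-9:
        raise ValueError("PLC identical across all observations; curve cannot be fit")

    # P50 guess: psi nearest 50% loss
    b0 = float(psi[np.argmin(np.abs(plc - 50.0))])
    if b0 == 0.0:
        b0 = float(np.median(psi))
    out: dict[str, FitResult] = {}

    starts_s = start_grid({"a": 2.0, "b": b0}, {"a": (0.25, 1.0, 4.0), "b": (0.7, 1.0, 1.4)})
    res_s = fit_multistart(
        "sigmoidal", lambda p: np.asarray(eval_vuln("sigmoidal", p, psi)), plc,
        starts_s, {"a": (1e-3, 1e3), "b": (-50.0, 0.0)})
    if res_s.success:
        a, b = res_s.params["a"], res_s.params["b"]
        res_s.extra.update({"P_50": b, "P_e": b + 2.0 / a, "P_max": b - 2.0 / a})
    out["sigmoidal"] = res_s

    bw0 = float(max(-b0, 0.5))
    starts_w = start_grid({"b_w": bw0, "c_w": 2.0},
                          {"b_w": (0.5, 1.0, 2.0), "c_w": (0.25, 1.0, 3.0)})
    res_w = fit_multistart(
        "weibull", lambda p: np.asarray(eval_vuln("weibull", p, psi)), plc,
        starts_w, {"b_w": (1e-3, 50.0), "c_w": (1e-2, 50.0)})
    if res_w.success:
        bw, cw = res_w.params["b_w"], res_w.params["c_w"]
        res_w.extra["P_50"] = -bw * np.log(2.0) ** (1.0 / cw)
    out["weibull"] = res_w

    for r in out.values():
        r.extra["data"] = {"psi": psi.tolist(), "PLC": plc.tolist()}
        r._plot_fn = _vuln_plot_fn(psi, plc, out)
    return out


def _vuln_plot_fn(psi, plc, results):
    def plot(_result: FitResult):
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(psi, plc, "ko", label="data")
        pg = np.linspace(psi.min(), min(psi.max(), 0.0), 300)
        for name, style in (("sigmoidal", "b-"), ("weibull", "r--")):
            r = results.get(name)
            if r is not None and r.success:
                ax.plot(pg, eval_vuln(name, r.params, pg), style, label=name)
        sig = results.get("sigmoidal")
        if sig is not None and sig.success:
            for key, c in (("P_e", "0.6"), ("P_50", "0.4"), ("P_max", "0.2")):
                ax.axvline(sig.extra[key], color=c, lw=0.8, ls=":")
        ax.set_xlabel(r"$\Psi$ (MPa)")
        ax.set_ylabel("PLC (%)")
        ax.legend(frameon=False)
        fig.tight_layout()
        return fig

    return plot


def fit_pv_curve(
    data: pd.DataFrame,
    *,
    dry_mass: float | None = None,
    saturated_mass: float | None = None,
    r2_threshold: float = 0.995,
    min_region: int = 4,
    n_bootstrap: int = 100,
) -> FitResult:
    """Fit a pressure-volume curve from (psi, RWC) or (psi, mass) data.

    The post-turgor-loss linear region of 1/|psi| vs (100 - RWC) is located
    by growing the point set from the driest end and keeping the largest set
    whose linear fit holds R^2 >= ``r2_threshold``.  Outputs: pi_o (osmotic
    potential at full turgor, MPa, with a delta-method SE), psi_TLP and
    RWC_TLP at the interpolated first zero-turgor crossing, C_ft (relative
    capacitance at full turgor, MPa-1) and the modulus of elasticity
    (MPa, dP/dRWC-fraction over the pre-TLP region).
    """
    sub = data.dropna(subset=["psi"]).copy()
    psi = _normalize_psi(np.asarray(sub["psi"], dtype=float), "fit_pv_curve")
    if "RWC" in sub:
        rwc = np.asarray(sub["RWC"], dtype=float)
    elif "mass" in sub:
        if dry_mass is None or saturated_mass is None:
            raise ValueError("mass input requires dry_mass and saturated_mass")
        rwc = 100.0 * (np.asarray(sub["mass"], dtype=float) - dry_mass) / (saturated_mass - dry_mass)
    else:
        raise ValueError("need an RWC or mass column")
    if psi.size < 8:
        raise ValueError(f"need >= 8 observations, got {psi.size}")
    if np.any(np.diff(rwc) > 1e-9):
        raise ValueError("observations must be ordered by declining RWC")

    core = _pv_core(psi, rwc, r2_threshold, min_region)
    res = _pv_result(psi, rwc, core)
    if n_bootstrap and psi.size >= min_region + 2:
        boot = _pv_bootstrap_se(psi, rwc, r2_threshold, min_region, n_bootstrap)
        # selection of the linear region varies with noise; the resampled SE
        # captures that where the within-region OLS SE cannot
        for k, v in boot.items():
            if np.isfinite(v):
                res.se[k] = max(float(v), res.se.get(k, 0.0))
    return res


def _pv_bootstrap_se(psi, rwc, r2_threshold, min_region, n_boot):
    rng = np.random.default_rng(0)  # fixed: identical input -> identical SEs
    n = psi.size
    draws: dict[str, list[float]] = {"pi_o": [], "psi_TLP": [], "RWC_TLP": []}
    for _ in range(n_boot):
        idx = np.sort(rng.integers(0, n, n))
        try:
            core = _pv_core(psi[idx], rwc[idx], r2_threshold, min_region)
        except ValueError:
            continue
        draws["pi_o"].append(core["pi_o"])
        draws["psi_TLP"].append(core["psi_TLP"])
        draws["RWC_TLP"].append(core["RWC_TLP"])
    out = {}
    for k, v in draws.items():
        v = np.asarray(v, dtype=float)
        v = v[np.isfinite(v)]
        out[k] = float(np.std(v, ddof=1)) if v.size >= max(10, n_boot // 2) else float("nan")
    return out


def _line_fit(xs: np.ndarray, ys: np.ndarray) -> tuple[float, float]:
    """Ordinary least-squares line; raises on a degenerate abscissa."""
    xm, ym = xs.mean(), ys.mean()
    sxx = float(np.sum((xs - xm) ** 2))
    if sxx < 1e-12:
        raise ValueError("degenerate regression: no spread in the regressor")
    slope = float(np.sum((xs - xm) * (ys - ym)) / sxx)
    return slope, float(ym - slope * xm)


def _pv_core(psi: np.ndarray, rwc: np.ndarray, r2_threshold: float, min_region: int) -> dict:
    """Region selection and parameter derivation for one PV data set."""
    x = 100.0 - rwc                      # water deficit, %
    y = 1.0 / np.abs(psi)                # MPa-1
    n = x.size

    # grow the linear region from the driest end (largest x)
    best = None          # (size, r2, slope, intercept, start_idx)
    fallback = None
    for start in range(n - min_region, -1, -1):
        xs, ys = x[start:], y[start:]
        try:
            slope, intercept = _line_fit(xs, ys)
        except ValueError:
            continue
        pred = slope * xs + intercept
        ss_res = float(np.sum((ys - pred) ** 2))
        ss_tot = float(np.sum((ys - ys.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        cand = (xs.size, r2, slope, intercept, start)
        if fallback is None or r2 > fallback[1]:
            fallback = cand
        if r2 >= r2_threshold and (best is None or xs.size > best[0]):
            best = cand
    warn_list = []
    if best is None:
        if fallback is None:
            raise ValueError(f"no linear region of >= {min_region} points found")
        warn_list.append(
            f"no region met R^2 >= {r2_threshold}; using best-R^2 region "
            f"(R^2 = {fallback[1]:.4f}, {fallback[0]} points)")
        best = fallback
    size, r2, slope, intercept, start = best
    if intercept <= 0:
        raise ValueError("non-positive 1/|psi| intercept; cannot derive pi_o "
                         "(is the linear region really post-turgor-loss?)")

    pi_o = -1.0 / intercept
    # delta-method SE from the region regression
    xs, ys = x[start:], y[start:]
    dof = max(xs.size - 2, 1)
    s2 = float(np.sum((ys - (slope * xs + intercept)) ** 2)) / dof
    Sxx = float(np.sum((xs - xs.mean()) ** 2))
    se_int = np.sqrt(s2 * (1.0 / xs.size + xs.mean() ** 2 / Sxx)) if Sxx > 0 else np.nan
    pi_o_se = float(se_int / intercept**2)

    # osmotic line over the whole curve and turgor
    with np.errstate(divide="ignore"):
        pi_line = -1.0 / (intercept + slope * x)
    turgor = psi - pi_line
    # first P = 0 crossing walking dry-ward from full hydration; a small
    # tolerance absorbs round-off when a grid point sits exactly at P = 0
    tol = 1e-9 * max(float(np.max(np.abs(psi))), 1.0)
    psi_tlp = rwc_tlp = np.nan
    below = np.nonzero(turgor <= tol)[0]
    if below.size == 0:
        warn_list.append("no zero-turgor crossing within the data; TLP reported as NaN")
    elif below[0] == 0:
        warn_list.append("turgor non-positive from the first point; TLP not bracketed")
    else:
        i, j = below[0] - 1, below[0]
        drop = turgor[i] - turgor[j]
        f = turgor[i] / drop if drop > 0 else 1.0
        psi_tlp = float(psi[i] + f * (psi[j] - psi[i]))
        rwc_tlp = float(rwc[i] + f * (rwc[j] - rwc[i]))

    # pre-TLP capacitance (RWC fraction per MPa) and elastic modulus
    pre = turgor > 0
    C_ft = elasticity = np.nan
    if pre.sum() >= 2:
        try:
            C_ft = _line_fit(psi[pre], rwc[pre] / 100.0)[0]
            elasticity = _line_fit(rwc[pre] / 100.0, turgor[pre])[0]
        except ValueError:
            pass

    return {
        "pi_o": float(pi_o), "psi_TLP": psi_tlp, "RWC_TLP": rwc_tlp,
        "C_ft": C_ft, "elasticity": elasticity, "pi_o_se": pi_o_se,
        "slope": float(slope), "intercept": float(intercept),
        "r2": float(r2), "size": int(size), "start": int(start),
        "ssr": float(np.sum((ys - (slope * xs + intercept)) ** 2)),
        "warnings": warn_list,
    }


def _pv_result(psi: np.ndarray, rwc: np.ndarray, core: dict) -> FitResult:
    x = 100.0 - rwc
    y = 1.0 / np.abs(psi)
    slope, intercept = core["slope"], core["intercept"]
    fitted = slope * x + intercept
    res = FitResult(
        model="pv",
        params={k: core[k] for k in ("pi_o", "psi_TLP", "RWC_TLP", "C_ft", "elasticity")},
        se={"pi_o": core["pi_o_se"]},
        ssr=core["ssr"],
        n_obs=x.size,
        fitted=fitted,
        residuals=y - fitted,
        warnings=list(core["warnings"]),
        extra={
            "region": {"n_points": core["size"], "r2": core["r2"],
                       "slope": slope, "intercept": intercept},
            "data": {"psi": psi.tolist(), "RWC": rwc.tolist()},
        },
    )
    res._plot_fn = _pv_plot_fn(psi, rwc, x, y, slope, intercept, core["start"])
    return res


def _pv_plot_fn(psi, rwc, x, y, slope, intercept, start):
    def plot(result: FitResult):
        import matplotlib.pyplot as plt

        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        # water-mass style panel: psi vs RWC
        ax1.plot(rwc, psi, "ko")
        ax1.set_xlabel("RWC (%)")
        ax1.set_ylabel(r"$\Psi$ (MPa)")
        ax1.invert_xaxis()
        # PV panel: 1/|psi| vs 100-RWC with the linear-region fit
        ax2.plot(x, y, "ko")
        xr = np.linspace(0.0, x.max(), 100)
        ax2.plot(xr, slope * xr + intercept, color="0.5",
                 label=f"linear region ({result.extra['region']['n_points']} pts)")
        ax2.plot(x[start:], y[start:], "o", mfc="none", mec="r", ms=10)
        ax2.set_xlabel("100 - RWC (%)")
        ax2.set_ylabel(r"$1/|\Psi|$ (MPa$^{-1}$)")
        ax2.legend(frameon=False)
        fig.tight_layout()
        return fig

    return plot
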
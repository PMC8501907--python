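"""Temperature responses of biological rates.

Seven model forms are provided, spanning the shapes used for enzyme-limited
photosynthetic parameters and leaf respiration:

``arrhenius``
    k = k_ref * exp(E_a (T - T_ref) / (T_ref R T)) — monotone exponential.
``medlyn_peaked``
    Arrhenius kernel times a deactivation term controlled by H_d (J mol-1)
    and an entropy parameter dS (J mol-1 K-1); peaked when H_d > E_a, with
    closed-form optimum T_opt = H_d / (dS - R ln(E_a / (H_d - E_a))).
``topt_peaked``
    The same peaked response re-parameterised directly in terms of the
    optimum (T_opt, K) and the rate there (k_opt).
``kruse``
    ln(k/k_ref) = E_a_ref x + (dEa/2) x^2 with x = (1/T_ref - 1/T)/R;
    reduces to Arrhenius when the curvature term dEa = 0.
``mmrt``
    Macromolecular rate theory: activation enthalpy/heat-capacity form,
    anchored so that k(T_ref) = k_ref.  Under that anchoring the activation
    entropy cancels from the temperature dependence, so the free parameters
    are (k_ref, dH, dCp).
``heskel``
    ln k = a + b t + c t^2 with t in degC (log-polynomial respiration form).
``quadratic``
    k = a + b t + c t^2 with t in degC.

Rates are in whatever unit the data carry (conventionally umol m-2 s-1);
temperatures in K; energies in J mol-1.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .constants import R_GAS, T_REF, T0_KELVIN
from .fitting import FitResult, fit_multistart, gaussian_ic, start_grid

__all__ = [
    "T_RESPONSE_MODELS",
    "eval_t_response",
    "fit_t_response",
    "peak_temperature",
]

T_RESPONSE_MODELS = (
    "arrhenius",
    "medlyn_peaked",
    "topt_peaked",
    "kruse",
    "mmrt",
    "heskel",
    "quadratic",
)

_PARAM_NAMES = {
    "arrhenius": ("k_ref", "E_a"),
    "medlyn_peaked": ("k_ref", "E_a", "H_d", "dS"),
    "topt_peaked": ("k_opt", "E_a", "H_d", "T_opt"),
    "kruse": ("k_ref", "E_a_ref", "dEa"),
    "mmrt": ("k_ref", "dH", "dCp"),
    "heskel": ("a", "b", "c"),
    "quadratic": ("a", "b", "c"),
}

_EXP_CAP = 700.0  # exp() overflow guard; beyond this the regime is unphysical


def _safe_exp(x: np.ndarray, model_id: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > _EXP_CAP):
        raise OverflowError(
            f"{model_id}: exponent magnitude exceeds {_EXP_CAP:g}; "
            "parameter regime produces non-finite rates"
        )
    return np.exp(x)


def eval_t_response(model_id: str, params: Mapping[str, float], T_leaf) -> np.ndarray | float:
    """Evaluate a temperature-response model at leaf temperature(s) in K."""
    T = np.asarray(T_leaf, dtype=float)
    scalar = T.ndim == 0
    T = np.atleast_1d(T)
    if np.any(T <= 0):
        raise ValueError("T_leaf must be positive (Kelvin)")
    p = params
    T_ref = float(p.get("T_ref", T_REF))

    if model_id == "arrhenius":
        k = p["k_ref"] * _safe_exp(p["E_a"] * (T - T_ref) / (T_ref * R_GAS * T), model_id)
    elif model_id == "medlyn_peaked":
        arrh = p["k_ref"] * _safe_exp(p["E_a"] * (T - T_ref) / (T_ref * R_GAS * T), model_id)
        num = 1.0 + _safe_exp((T_ref * p["dS"] - p["H_d"]) / (T_ref * R_GAS), model_id)
        den = 1.0 + _safe_exp((T * p["dS"] - p["H_d"]) / (T * R_GAS), model_id)
        k = arrh * num / den
    elif model_id == "topt_peaked":
        To, Hd, Ea = p["T_opt"], p["H_d"], p["E_a"]
        num = Hd * _safe_exp(Ea * (T - To) / (T * R_GAS * To), model_id)
        den = Hd - Ea * (1.0 - _safe_exp(Hd * (T - To) / (T * R_GAS * To), model_id))
        k = p["k_opt"] * num / den
    elif model_id == "kruse":
        x = (1.0 / T_ref - 1.0 / T) / R_GAS
        k = p["k_ref"] * _safe_exp(p["E_a_ref"] * x + 0.5 * p["dEa"] * x**2, model_id)
    elif model_id == "mmrt":
        # anchored at T_ref; dS cancels (see module docstring)
        dH, dCp = p["dH"], p["dCp"]

        def _lnk(TT):
            return (-(dH + dCp * (TT - T_ref)) / (R_GAS * TT)
                    + dCp * np.log(TT / T_ref) / R_GAS)

        k = p["k_ref"] * _safe_exp(_lnk(T) - _lnk(np.array(T_ref)), model_id)
    elif model_id == "heskel":
        t = T - T0_KELVIN
        k = _safe_exp(p["a"] + p["b"] * t + p["c"] * t**2, model_id)
    elif model_id == "quadratic":
        t = T - T0_KELVIN
        k = p["a"] + p["b"] * t + p["c"] * t**2
    else:
        raise ValueError(f"unknown temperature-response model {model_id!r}; "
                         f"choose from {T_RESPONSE_MODELS}")
    if not np.all(np.isfinite(k)):
        raise OverflowError(f"{model_id}: non-finite rate in this parameter regime")
    return float(k[0]) if scalar else k


def peak_temperature(E_a: float, H_d: float, dS: float) -> float:
    """Closed-form optimum temperature of the medlyn_peaked model (K).

    Requires H_d > E_a (otherwise the response has no interior maximum).
    """
    if H_d <= E_a:
        raise ValueError("peaked response requires H_d > E_a")
    return H_d / (dS - R_GAS * np.log(E_a / (H_d - E_a)))


def _starts_for(model_id: str, T: np.ndarray, k: np.ndarray, T_ref: float) -> list[dict]:
    """Moment-based starting guesses plus spread grids (looped starting values)."""
    k_pos = np.clip(k, 1e-9, None)
    i_ref = int(np.argmin(np.abs(T - T_ref)))
    k_ref0 = float(k_pos[i_ref])
    # Arrhenius slope guess from ln k vs (T - T_ref)/(T_ref T)
    xa = (T - T_ref) / (T_ref * T)
    with np.errstate(all="ignore"):
        Ea0 = float(np.polyfit(xa, np.log(k_pos), 1)[0] * R_GAS)
    Ea0 = float(np.clip(Ea0, 1e3, 3e5))
    spread3 = (0.3, 1.0, 3.0)
    if model_id == "arrhenius":
        return start_grid({"k_ref": k_ref0, "E_a": Ea0},
                          {"k_ref": (0.5, 1.0, 2.0), "E_a": spread3})
    if model_id == "medlyn_peaked":
        base = {"k_ref": k_ref0, "E_a": max(Ea0, 3e4), "H_d": 2e5, "dS": 650.0}
        return start_grid(base, {"E_a": (0.5, 1.0, 2.0), "H_d": (0.75, 1.0, 1.5),
                                 "dS": (0.92, 1.0, 1.08)})
    if model_id == "topt_peaked":
        i_max = int(np.argmax(k))
        base = {"k_opt": float(k_pos[i_max]), "E_a": max(Ea0, 3e4),
                "H_d": 2e5, "T_opt": float(T[i_max])}
        return start_grid(base, {"E_a": (0.5, 1.0, 2.0), "H_d": (0.75, 1.0, 1.5),
                                 "T_opt": (0.98, 1.0, 1.02)})
    if model_id == "kruse":
        return start_grid({"k_ref": k_ref0, "E_a_ref": Ea0, "dEa": 0.0},
                          {"E_a_ref": spread3, "dEa": (-1e5, 0.0, 1e5)})
    if model_id == "mmrt":
        return start_grid({"k_ref": k_ref0, "dH": max(Ea0, 2e4), "dCp": 0.0},
                          {"dH": (0.5, 1.0, 2.0), "dCp": (-2000.0, 0.0, 2000.0)})
    raise AssertionError(model_id)


def fit_t_response(
    data: pd.DataFrame,
    models: Iterable[str] = T_RESPONSE_MODELS,
    *,
    rate_col: str = "rate",
    T_ref: float = T_REF,
) -> dict[str, FitResult]:
    """Fit the requested temperature-response models to (rate, T_leaf) data.

    Each nonlinear model is fit by least squares restarted over a grid of
    starting values; the linear-in-parameters forms (quadratic, and heskel on
    the log scale for its start) are solved directly.  A failed model yields
    a flagged FitResult and does not block the others.

    Returns an ordered mapping model_id -> FitResult.
    """
    models = list(models)
    unknown = [m for m in models if m not in T_RESPONSE_MODELS]
    if unknown:
        raise ValueError(f"unknown model(s): {unknown}; choose from {T_RESPONSE_MODELS}")
    T = np.asarray(data["T_leaf"], dtype=float)
    k = np.asarray(data[rate_col], dtype=float)
    keep = np.isfinite(T) & np.isfinite(k)
    T, k = T[keep], k[keep]

    out: dict[str, FitResult] = {}
    for m in models:
        n_par = len(_PARAM_NAMES[m])
        if T.size < n_par + 2:
            raise ValueError(f"{m}: need at least {n_par + 2} observations, got {T.size}")
        if m == "quadratic":
            out[m] = _fit_polynomial(m, T, k, log_scale=False)
        elif m == "heskel":
            out[m] = _fit_heskel(T, k)
        else:
            starts = _starts_for(m, T, k, T_ref)
            bounds = _BOUNDS[m]

            def predict(p, m=m):
                try:
                    return np.asarray(eval_t_response(m, {**p, "T_ref": T_ref}, T))
                except OverflowError:
                    return np.full_like(T, 1e30)

            res = fit_multistart(m, predict, k, starts, bounds)
            res.extra["T_ref"] = T_ref
            out[m] = res
        out[m].extra["data"] = {"T_leaf": T.tolist(), rate_col: k.tolist()}
        out[m]._plot_fn = _make_plot_fn(m, T, k, T_ref)
    return out


_BOUNDS = {
    "arrhenius": {"k_ref": (1e-9, np.inf), "E_a": (-5e5, 5e5)},
    "medlyn_peaked": {"k_ref": (1e-9, np.inf), "E_a": (1e2, 5e5),
                      "H_d": (1e3, 3e6), "dS": (1.0, 5e3)},
    "topt_peaked": {"k_opt": (1e-9, np.inf), "E_a": (1e2, 5e5),
                    "H_d": (1e3, 3e6), "T_opt": (250.0, 370.0)},
    "kruse": {"k_ref": (1e-9, np.inf), "E_a_ref": (-5e5, 5e5), "dEa": (-1e7, 1e7)},
    "mmrt": {"k_ref": (1e-9, np.inf), "dH": (-5e5, 5e5), "dCp": (-1e5, 1e5)},
}


def _fit_polynomial(model_id: str, T: np.ndarray, k: np.ndarray, *, log_scale: bool) -> FitResult:
    t = T - T0_KELVIN
    y = np.log(np.clip(k, 1e-12, None)) if log_scale else k
    X = np.column_stack([np.ones_like(t), t, t**2])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted_lin = X @ beta
    fitted = np.exp(fitted_lin) if log_scale else fitted_lin
    resid = k - fitted
    ssr = float(np.sum(resid**2))
    dof = max(t.size - 3, 1)
    scale_resid = y - fitted_lin
    s2 = float(np.sum(scale_resid**2)) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    aic, bic = gaussian_ic(float(np.sum(scale_resid**2)), t.size, 3)
    return FitResult(
        model=model_id,
        params={"a": float(beta[0]), "b": float(beta[1]), "c": float(beta[2])},
        se={"a": float(se[0]), "b": float(se[1]), "c": float(se[2])},
        ssr=ssr, aic=aic, bic=bic, n_obs=t.size,
        fitted=fitted, residuals=resid,
    )


def _fit_heskel(T: np.ndarray, k: np.ndarray) -> FitResult:
    """Heskel log-polynomial: OLS on ln k gives the start, NLS on k refines."""
    ols = _fit_polynomial("heskel", T, k, log_scale=True)
    starts = start_grid(ols.params, {"a": (0.9, 1.0, 1.1)})

    def predict(p):
        try:
            return np.asarray(eval_t_response("heskel", p, T))
        except OverflowError:
            return np.full_like(T, 1e30)

    res = fit_multistart("heskel", predict, k, starts)
    return res if res.success else ols


def _make_plot_fn(model_id: str, T: np.ndarray, k: np.ndarray, T_ref: float):
    def plot(result: FitResult):
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(T - T0_KELVIN, k, "ko", label="data")
        if result.success:
            Tg = np.linspace(T.min(), T.max(), 200)
            kg = eval_t_response(model_id, {**result.params, "T_ref": T_ref}, Tg)
            ax.plot(Tg - T0_KELVIN, kg, "b-", label=f"{model_id} fit")
        ax.set_xlabel("T_leaf (degC)")
        ax.set_ylabel("rate")
        ax.legend(frameon=False)
        fig.tight_layout()
        return fig

    return plot
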
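"""Generic nonlinear-least-squares machinery shared by all fitting modules.

Every curve fit in the package goes through :func:`fit_multistart`: nonlinear
least squares restarted over a grid of starting values, keeping the
lowest-SSR converged solution.  Multiple restarts guard against the local
minima that plague single-start NLS on ecophysiological response curves
(peaked temperature responses and min-rule CO2 responses in particular).

Standard errors come from the usual Gauss-Newton covariance
``s^2 (J'J)^-1`` evaluated at the optimum; AIC/BIC use the Gaussian
log-likelihood (the error variance counts as a parameter), matching the
conventions of R's ``nls``/``AIC``.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = ["FitResult", "fit_multistart", "start_grid", "gaussian_ic"]


@dataclass
class FitResult:
    """Result of one curve fit.

    Attributes
    ----------
    model:
        Identifier of the fitted model (e.g. ``"aq"``, ``"arrhenius"``).
    params, se:
        Point estimates and standard errors, keyed by parameter name.
    ssr, aic, bic:
        Sum of squared residuals and information criteria.
    fitted, residuals:
        Per-observation model values and ``observed - fitted``.
    success:
        False when no restart converged; ``message`` then carries diagnostics.
    warnings:
        Non-fatal flags (unidentifiable parameters, SE explosions, ...).
    extra:
        Model-specific payload (modelled-data tables, derived parameters).
    """

    model: str
    params: dict[str, float] = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)
    ssr: float = math.nan
    aic: float = math.nan
    bic: float = math.nan
    n_obs: int = 0
    fitted: np.ndarray | None = None
    residuals: np.ndarray | None = None
    success: bool = True
    message: str = ""
    warnings: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)
    _plot_fn: Callable[["FitResult"], object] | None = field(default=None, repr=False, compare=False)

    def plot(self):
        """Build and return the matplotlib Figure for this fit."""
        if self._plot_fn is None:
            raise ValueError(f"no plot defined for model {self.model!r}")
        return self._plot_fn(self)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "success": self.success,
            "params": self.params,
            "se": self.se,
            "ssr": self.ssr,
            "aic": self.aic,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "warnings": self.warnings,
            "message": self.message,
            **{k: v for k, v in self.extra.items() if _jsonable(v)},
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, default=_json_default)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def __repr__(self) -> str:  # compact, parameters first
        ps = ", ".join(f"{k}={v:.6g}" for k, v in self.params.items())
        return f"<FitResult {self.model}: {ps}; ssr={self.ssr:.4g}, ok={self.success}>"


def _jsonable(v) -> bool:
    return isinstance(v, (int, float, str, bool, list, dict, type(None)))


def _json_default(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    raise TypeError(f"not JSON serializable: {type(v)}")


def gaussian_ic(ssr: float, n: int, k: int) -> tuple[float, float]:
    """AIC and BIC from a Gaussian likelihood with k mean parameters."""
    ssr = max(ssr, 1e-300)
    loglik = -0.5 * n * (math.log(2 * math.pi) + math.log(ssr / n) + 1.0)
    k_eff = k + 1  # error variance
    return 2 * k_eff - 2 * loglik, math.log(n) * k_eff - 2 * loglik


def start_grid(
    base: Mapping[str, float],
    spreads: Mapping[str, Sequence[float]] | None = None,
    *,
    max_starts: int = 500,
) -> list[dict[str, float]]:
    """Build a grid of starting-value dictionaries around moment-based guesses.

    ``spreads`` gives multiplicative factors per parameter (additive offsets
    for parameters whose base is 0).  The Cartesian product is truncated at
    ``max_starts``.
    """
    spreads = spreads or {}
    axes = []
    names = list(base)
    for name in names:
        factors = spreads.get(name, (1.0,))
        b = base[name]
        if b == 0.0:
            axes.append([f - 1.0 for f in factors])
        else:
            axes.append([b * f for f in factors])
    grid = [dict(zip(names, combo)) for combo in itertools.product(*axes)]
    return grid[:max_starts]


def fit_multistart(
    model_id: str,
    predict: Callable[[Mapping[str, float]], np.ndarray],
    y: np.ndarray,
    starts: Sequence[Mapping[str, float]],
    bounds: Mapping[str, tuple[float, float]] | None = None,
    *,
    xtol: float = 1e-12,
    ftol: float = 1e-12,
    max_nfev: int = 1000,
) -> FitResult:
    """Nonlinear least squares restarted over ``starts``; lowest SSR wins.

    Parameters
    ----------
    predict
        Maps a parameter dict to predicted responses (same length as ``y``).
    starts
        Starting-value dicts; all must share the same parameter names.
    bounds
        Optional ``name -> (lo, hi)`` box constraints.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    names = list(starts[0])
    bounds = bounds or {}
    lo = np.array([bounds.get(nm, (-np.inf, np.inf))[0] for nm in names])
    hi = np.array([bounds.get(nm, (-np.inf, np.inf))[1] for nm in names])

    def resid(theta: np.ndarray) -> np.ndarray:
        return predict(dict(zip(names, theta))) - y

    best = None
    errors: list[str] = []
    for s in starts:
        x0 = np.clip(np.array([float(s[nm]) for nm in names]), lo, hi)
        try:
            sol = least_squares(
                resid, x0, bounds=(lo, hi), xtol=xtol, ftol=ftol, gtol=None, max_nfev=max_nfev
            )
        except Exception as exc:  # noqa: BLE001 - collected as diagnostics
            errors.append(str(exc))
            continue
        if not np.all(np.isfinite(sol.fun)):
            continue
        ssr = float(sol.cost * 2.0)
        if sol.success and (best is None or ssr < best.cost * 2.0 - 1e-15):
            best = sol

    k = len(names)
    if best is None:
        msg = "no start converged"
        if errors:
            msg += f"; first errors: {errors[:3]}"
        return FitResult(model=model_id, success=False, n_obs=n, message=msg)

    theta = best.x
    params = dict(zip(names, map(float, theta)))
    fitted = predict(params)
    residuals = y - fitted
    ssr = float(np.sum(residuals**2))
    dof = max(n - k, 1)
    s2 = ssr / dof
    J = best.jac
    JtJ = J.T @ J
    try:
        cov = s2 * np.linalg.inv(JtJ)
        singular = False
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(JtJ)
        singular = True
    se_vec = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    # a (near-)zero Jacobian column means the data carry no information on
    # that parameter: its uncertainty is unbounded, not zero
    col_norms = np.linalg.norm(J, axis=0)
    dead = col_norms < 1e-10 * max(1.0, float(col_norms.max()))
    se_vec[dead] = np.inf
    se = dict(zip(names, se_vec))
    aic, bic = gaussian_ic(ssr, n, k)
    result = FitResult(
        model=model_id,
        params=params,
        se={k_: float(v) for k_, v in se.items()},
        ssr=ssr,
        aic=aic,
        bic=bic,
        n_obs=n,
        fitted=fitted,
        residuals=residuals,
    )
    if singular:
        result.warnings.append("singular information matrix; standard errors from pseudo-inverse")
    for nm, d in zip(names, dead):
        if d:
            result.warnings.append(f"data carry no local information on {nm}; SE unbounded")
    for nm in names:
        est, s_ = params[nm], result.se[nm]
        if abs(est) > 0 and np.isfinite(s_) and s_ / abs(est) > 1.0:
            result.warnings.append(
                f"large standard error on {nm} (SE/estimate = {s_ / abs(est):.2f}); "
                "parameter may be unidentifiable"
            )
    # active box constraints undermine the covariance approximation
    at_bound = [nm for nm, t, l_, h_ in zip(names, theta, lo, hi) if t <= l_ + 1e-12 or t >= h_ - 1e-12]
    if at_bound:
        result.warnings.append(f"estimate(s) at bound: {', '.join(at_bound)}")
    return result
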
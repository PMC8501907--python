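"""Forward simulation of C3 photosynthesis (FvCB) with a CO2 supply line.

Demand is the FvCB minimum rule evaluated at the chloroplastic CO2 mole
fraction C_c; supply is diffusion down the air-to-chloroplast gradient,
``A = g_tc (C_air - C_c)``.  :func:`solve_cc` finds the C_c at which the two
balance by bracketed root finding, and :func:`simulate_photosynthesis` maps
the solver over a parameter grid.

Electron transport responds to light through the non-rectangular hyperbola
with (phi_J, theta_J, J_max); capacities and kinetic constants are scaled
from their 25 degC values to T_leaf with Arrhenius responses.

Leaf temperature is a required input.  An external energy-balance solver can
be plugged in by computing T_leaf upstream and passing it in EnvParams; no
energy-balance model ships with the package.
"""

from __future__ import annotations

import difflib
import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import constants
from .co2_light import kinetics_at_temperature
from .temp_response import eval_t_response

__all__ = ["LeafParams", "EnvParams", "SimResult", "make_parameters",
           "solve_cc", "simulate_photosynthesis"]


@dataclass(frozen=True)
class LeafParams:
    """Leaf biochemical parameters (25 degC basis + temperature scaling)."""
    V_cmax25: float
    J_max25: float
    V_TPU25: float
    R_d25: float
    Gamma_star25: float
    K_c25: float
    K_o25: float
    phi_J: float
    theta_J: float
    g_mc: float
    V_cmax_Ea: float
    J_max_Ea: float
    R_d_Ea: float
    K_c_Ea: float
    K_o_Ea: float
    Gamma_star_Ea: float

    def __post_init__(self):
        if self.g_mc <= 0:
            raise ValueError("g_mc must be positive")
        for nm in ("V_cmax25", "J_max25", "V_TPU25", "R_d25"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be non-negative")


@dataclass(frozen=True)
class EnvParams:
    """Environmental drivers for one simulation."""
    C_air: float
    Q: float
    T_leaf: float
    O: float
    g_tc: float

    def __post_init__(self):
        if self.C_air <= 0:
            raise ValueError("C_air must be positive")
        if self.g_tc <= 0:
            raise ValueError("g_tc must be positive")


@dataclass
class SimResult:
    """Solved state of one leaf under one environment."""
    C_c: float
    A_net: float
    limitation: str            # "Ac" | "Aj" | "Ap"
    A_c: float
    A_j: float
    A_p: float
    J: float
    V_cmax: float
    R_d: float
    Gamma_star: float
    K_m: float
    residual: float

    def as_row(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


_LEAF_KEYS = set(LeafParams.__dataclass_fields__)
_ENV_KEYS = set(EnvParams.__dataclass_fields__)


def make_parameters(overrides: Mapping[str, float] | None = None) -> tuple[LeafParams, EnvParams, dict]:
    """Build (LeafParams, EnvParams) from documented defaults plus overrides.

    Returns the two parameter sets and a provenance dict recording, per
    field, whether the value was a default or an override.  Unknown override
    keys raise with nearest-name suggestions.
    """
    overrides = dict(overrides or {})
    leaf_vals = {k: constants.LEAF_DEFAULTS[k] for k in _LEAF_KEYS}
    env_vals = {k: constants.ENV_DEFAULTS[k] for k in _ENV_KEYS}
    provenance = {k: "default" for k in itertools.chain(leaf_vals, env_vals)}
    vocab = sorted(_LEAF_KEYS | _ENV_KEYS)
    for key, val in overrides.items():
        if key in _LEAF_KEYS:
            leaf_vals[key] = float(val)
        elif key in _ENV_KEYS:
            env_vals[key] = float(val)
        else:
            hints = difflib.get_close_matches(key, vocab, n=3, cutoff=0.4)
            hint = f"; did you mean {', '.join(hints)}?" if hints else ""
            raise KeyError(f"unknown parameter {key!r}{hint}")
        provenance[key] = "override"
    return LeafParams(**leaf_vals), EnvParams(**env_vals), provenance


def _temperature_adjusted(leaf: LeafParams, env: EnvParams) -> dict[str, float]:
    T = env.T_leaf
    arr = lambda k25, Ea: float(eval_t_response(  # noqa: E731
        "arrhenius", {"k_ref": k25, "E_a": Ea, "T_ref": constants.T_REF}, T))
    kin = kinetics_at_temperature(T, {
        "Gamma_star25": leaf.Gamma_star25, "K_c25": leaf.K_c25, "K_o25": leaf.K_o25,
        "Gamma_star_Ea": leaf.Gamma_star_Ea, "K_c_Ea": leaf.K_c_Ea, "K_o_Ea": leaf.K_o_Ea,
    })
    return {
        "V_cmax": arr(leaf.V_cmax25, leaf.V_cmax_Ea),
        "J_max": arr(leaf.J_max25, leaf.J_max_Ea),
        "V_TPU": arr(leaf.V_TPU25, leaf.R_d_Ea),  # TPU scaled like respiration
        "R_d": arr(leaf.R_d25, leaf.R_d_Ea),
        "Gamma_star": kin["Gamma_star"],
        "K_m": kin["K_c"] * (1.0 + env.O / kin["K_o"]),
    }


def _electron_transport(Q: float, J_max: float, phi_J: float, theta_J: float) -> float:
    s = phi_J * Q + J_max
    if theta_J == 0.0:
        return phi_J * Q * J_max / s if s > 0 else 0.0
    disc = max(s * s - 4.0 * theta_J * phi_J * Q * J_max, 0.0)
    return (s - np.sqrt(disc)) / (2.0 * theta_J)


def solve_cc(leaf: LeafParams, env: EnvParams) -> SimResult:
    """Solve the supply-demand balance for chloroplastic CO2.

    Finds the root of ``demand(C_c) - supply(C_c)`` on (0, C_air + 500) by
    Brent's method and polishes it so the residual is below 1e-10.
    """
    tp = _temperature_adjusted(leaf, env)
    J = _electron_transport(env.Q, tp["J_max"], leaf.phi_J, leaf.theta_J)
    V_cmax, V_TPU, R_d = tp["V_cmax"], tp["V_TPU"], tp["R_d"]
    G, K_m = tp["Gamma_star"], tp["K_m"]
    A_p = 3.0 * V_TPU

    def rates(cc: float) -> tuple[float, float, float]:
        A_c = V_cmax * (cc - G) / (cc + K_m)
        A_j = J * (cc - G) / (4.0 * cc + 8.0 * G)
        return A_c, A_j, A_p

    def f(cc: float) -> float:
        A_c, A_j, _ = rates(cc)
        return (min(A_c, A_j, A_p) - R_d) - env.g_tc * (env.C_air - cc)

    lo, hi = 1e-6, env.C_air + 500.0
    f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no supply-demand sign change in ({lo:g}, {hi:g}): "
            f"f(lo)={f_lo:.6g}, f(hi)={f_hi:.6g}"
        )
    cc = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    # polish with bisection until the residual (umol m-2 s-1) is tiny
    res = f(cc)
    if abs(res) > 1e-11:
        a, b = max(lo, cc - 1e-6), min(hi, cc + 1e-6)
        fa = f(a)
        for _ in range(200):
            cc = 0.5 * (a + b)
            res = f(cc)
            if abs(res) <= 1e-12:
                break
            if fa * res < 0:
                b = cc
            else:
                a, fa = cc, res
    A_c, A_j, _ = rates(cc)
    realized = {"Ac": A_c, "Aj": A_j, "Ap": A_p}
    limitation = min(realized, key=realized.get)
    A_net = realized[limitation] - R_d
    return SimResult(
        C_c=float(cc), A_net=float(A_net), limitation=limitation,
        A_c=float(A_c), A_j=float(A_j), A_p=float(A_p), J=float(J),
        V_cmax=float(V_cmax), R_d=float(R_d), Gamma_star=float(G),
        K_m=float(K_m), residual=float(f(cc)),
    )


def simulate_photosynthesis(
    param_grid: Iterable[tuple[LeafParams, EnvParams]] | None = None,
    *,
    axes: Mapping[str, Sequence[float]] | None = None,
    base_overrides: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate photosynthesis over a parameter set.

    Either pass an explicit iterable of (LeafParams, EnvParams) pairs, or
    give ``axes`` mapping parameter names to level sequences: the Cartesian
    product of all axes (on top of defaults plus ``base_overrides``) is
    simulated.  A failed solve becomes a flagged row, not a crashed run.
    """
    combos: list[tuple[dict, LeafParams, EnvParams]] = []
    if param_grid is not None:
        combos = [({}, leaf, env) for leaf, env in param_grid]
    elif axes:
        names = list(axes)
        for values in itertools.product(*(axes[nm] for nm in names)):
            ov = dict(base_overrides or {})
            ov.update(dict(zip(names, values)))
            leaf, env, _ = make_parameters(ov)
            combos.append((dict(zip(names, values)), leaf, env))
    if not combos:
        raise ValueError("empty parameter grid")
    rows = []
    for tag, leaf, env in combos:
        row = dict(tag)
        row.update({"C_air": env.C_air, "Q": env.Q, "T_leaf": env.T_leaf,
                    "g_tc": env.g_tc, "O": env.O})
        try:
            sim = solve_cc(leaf, env)
            row.update(sim.as_row())
            row["failed"] = False
        except Exception as exc:  # noqa: BLE001 - per-row failure isolation
            row.update({"failed": True, "error": str(exc)})
        rows.append(row)
    return pd.DataFrame(rows)
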
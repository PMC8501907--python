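"""Synthetic gas-exchange, hydraulic and pressure-volume curve generation.

Every fitting routine in the package can be exercised without instrument
data: :func:`generate_synthetic_curve` evaluates the corresponding forward
model at known true parameters over realistic driver grids, adds seeded
Gaussian noise, and (optionally) renames columns into an instrument dialect
so the nomenclature translation layer is exercised too.

The default driver designs mirror common measurement protocols: light
responses at irradiances of 1500, 375, 150, 125, 100, 75, 50 and 25
umol m-2 s-1 plus a dark point; CO2 responses over 12 Ci set-points between
50 and 1500 umol mol-1 at 25 degC; temperature responses over 278-328 K.
True parameters are embedded in ``DataFrame.attrs["true_params"]`` for
recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .co2_light import eval_aq, eval_fvcb_ci, kinetics_at_temperature
from .constants import T_REF
from .core_data import CANONICAL_UNITS, invert_varname_map, load_varname_map
from .hydraulics import eval_vuln
from .stomata import eval_gs_model
from .temp_response import eval_t_response

__all__ = ["CurveDesign", "generate_synthetic_curve", "CURVE_KINDS", "DEFAULT_TRUE_PARAMS"]

CURVE_KINDS = ("aq", "aci", "t_response", "gs", "r_light_kok", "r_light_yin",
               "r_light_walker_ort", "gmc_variableJ", "pv", "vuln")

#: Default true parameters per curve kind (the study conditions).
DEFAULT_TRUE_PARAMS: dict[str, dict] = {
    "aq": {"A_sat": 25.0, "phi_J": 0.05, "theta_J": 0.85, "R_d": 1.2},
    "aci": {"V_cmax": 100.0, "J_max": 180.0, "V_TPU": 12.0, "R_d": 1.5},
    "t_response": {"model": "arrhenius", "k_ref": 75.0, "E_a": 55000.0},
    "gs": {"model": "ballberry", "g0": 0.02, "g1": 9.0},
    "r_light_kok": {"slope": 0.04, "R_light": 1.0},
    "r_light_yin": {"slope": 0.45, "R_light": 0.8},
    "r_light_walker_ort": {"C_i_star": 40.0, "R_light": 1.1,
                           "slopes": (0.02, 0.035, 0.05, 0.065, 0.08, 0.09, 0.1, 0.11)},
    "gmc_variableJ": {"g_mc": 0.25, "Gamma_star": 42.75, "R_light": 1.0},
    "pv": {"pi_o": -1.2, "RWC_TLP": 92.0},
    "vuln": {"model": "sigmoidal", "a": 2.0, "b": -2.5},
}

#: Default noise SD per kind, in response units.
DEFAULT_NOISE_SD: dict[str, float] = {
    "aq": 0.3, "aci": 0.5, "t_response": 1.0, "gs": 0.005,
    "r_light_kok": 0.05, "r_light_yin": 0.05, "r_light_walker_ort": 0.05,
    "gmc_variableJ": 0.1, "pv": 0.01, "vuln": 2.0,
}

#: Paper-protocol light levels for CO2-by-light campaigns plus a dark point.
AQ_LIGHT_LEVELS = (0.0, 25.0, 50.0, 75.0, 100.0, 125.0, 150.0, 375.0, 1500.0)
#: Leaf temperatures (degC) of a CO2-by-temperature campaign.
ACI_TEMPERATURES_C = (17.5, 20.0, 22.5, 25.0, 27.5, 30.0, 32.5, 35.0, 37.5, 40.0)


@dataclass(frozen=True)
class CurveDesign:
    """Specification for one synthetic curve (or curve family)."""
    kind: str
    true_params: Mapping = _field(default_factory=dict)
    drivers: Mapping[str, Sequence[float]] = _field(default_factory=dict)
    noise_sd: float | None = None
    seed: int = 0
    dialect: str = "canonical"

    def __post_init__(self):
        if self.kind not in CURVE_KINDS:
            raise ValueError(f"unknown curve kind {self.kind!r}; choose from {CURVE_KINDS}")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_synthetic_curve(design: CurveDesign) -> pd.DataFrame:
    """Generate a canonical observation table from a :class:`CurveDesign`.

    Identical (design, seed) pairs produce identical tables.  True
    parameters are stored in ``attrs["true_params"]``; the applied noise SD
    in ``attrs["noise_sd"]``.
    """
    params = {**DEFAULT_TRUE_PARAMS[design.kind], **dict(design.true_params)}
    sd = DEFAULT_NOISE_SD[design.kind] if design.noise_sd is None else float(design.noise_sd)
    rng = np.random.default_rng(design.seed)
    maker = _MAKERS[design.kind]
    table = maker(params, dict(design.drivers), sd, rng)
    table.attrs["true_params"] = params
    table.attrs["noise_sd"] = sd
    table.attrs["units"] = {c: CANONICAL_UNITS[c] for c in table.columns if c in CANONICAL_UNITS}
    if design.dialect != "canonical":
        varnames = load_varname_map(design.dialect)
        rename = {canon: src for canon, src in invert_varname_map(varnames).items()
                  if canon in table.columns}
        attrs = table.attrs
        table = table.rename(columns=rename)
        table.attrs = attrs
        table.attrs["dialect"] = design.dialect
    return table


def _make_aq(p, drivers, sd, rng):
    Q = np.asarray(drivers.get("Q", AQ_LIGHT_LEVELS), dtype=float)
    A = np.asarray(eval_aq(p, Q)) + rng.normal(0.0, sd, Q.size)
    return pd.DataFrame({"Q": Q, "A_net": A})


def _make_aci(p, drivers, sd, rng):
    C_i = np.asarray(drivers.get(
        "C_i", (50, 100, 150, 200, 300, 400, 500, 650, 800, 1000, 1250, 1500)), dtype=float)
    T_c = np.atleast_1d(np.asarray(drivers.get("T_leaf_C", 25.0), dtype=float))
    frames = []
    for t_c in T_c:
        T_k = t_c + 273.15
        kin = kinetics_at_temperature(T_k)
        m = eval_fvcb_ci({**p, "J": p.get("J", p.get("J_max")), **kin}, C_i)
        A = m["A_mod"].to_numpy() + rng.normal(0.0, sd, C_i.size)
        frames.append(pd.DataFrame({
            "C_i": C_i, "A_net": A, "Q": 1500.0, "T_leaf": T_k,
        }))
    return pd.concat(frames, ignore_index=True)


def _make_t_response(p, drivers, sd, rng):
    T = np.asarray(drivers.get("T_leaf", np.linspace(278.0, 328.0, 11)), dtype=float)
    model = p.pop("model") if "model" in p else "arrhenius"
    k = np.asarray(eval_t_response(model, p, T)) + rng.normal(0.0, sd, T.size)
    p["model"] = model
    return pd.DataFrame({"T_leaf": T, "rate": k})


def _make_gs(p, drivers, sd, rng):
    A = np.asarray(drivers.get("A_net", np.linspace(2.0, 24.0, 12)), dtype=float)
    n = A.size
    C_s = np.asarray(drivers.get("C_s", np.linspace(420.0, 330.0, n)), dtype=float)
    RH = np.asarray(drivers.get("RH", np.linspace(0.75, 0.45, n)), dtype=float)
    D = np.asarray(drivers.get("D", np.linspace(0.8, 2.6, n)), dtype=float)
    model = p.get("model", "ballberry")
    mp = {k: v for k, v in p.items() if k != "model"}
    g = np.asarray(eval_gs_model(model, mp, {"A_net": A, "C_s": C_s, "RH": RH, "D": D}))
    g = g + rng.normal(0.0, sd, n)
    return pd.DataFrame({"A_net": A, "C_s": C_s, "RH": RH, "D": D, "g_sw": g})


def _make_r_light_kok(p, drivers, sd, rng):
    Q = np.asarray(drivers.get("Q", np.arange(40.0, 101.0, 10.0)), dtype=float)
    A = p["slope"] * Q - p["R_light"] + rng.normal(0.0, sd, Q.size)
    return pd.DataFrame({"Q": Q, "A_net": A})


def _make_r_light_yin(p, drivers, sd, rng):
    Q = np.asarray(drivers.get("Q", np.arange(40.0, 101.0, 10.0)), dtype=float)
    # PSII efficiency declines gently with light in the Kok window
    phi = np.asarray(drivers.get("phi_PSII", 0.78 - 0.0012 * Q), dtype=float)
    x = Q * phi / 4.0
    A = p["slope"] * x - p["R_light"] + rng.normal(0.0, sd, Q.size)
    return pd.DataFrame({"Q": Q, "phi_PSII": phi, "A_net": A})


def _make_r_light_walker_ort(p, drivers, sd, rng):
    C_i = np.asarray(drivers.get("C_i", (20.0, 60.0, 100.0, 140.0, 180.0)), dtype=float)
    slopes = np.asarray(p["slopes"], dtype=float)
    Q_levels = np.asarray(drivers.get("Q", 100.0 + 150.0 * np.arange(slopes.size)), dtype=float)
    frames = []
    for q, s in zip(Q_levels, slopes):
        A = s * (C_i - p["C_i_star"]) - p["R_light"] + rng.normal(0.0, sd, C_i.size)
        frames.append(pd.DataFrame({"C_i": C_i, "A_net": A, "Q": q}))
    return pd.concat(frames, ignore_index=True)


def _make_gmc_variableJ(p, drivers, sd, rng):
    A = np.asarray(drivers.get("A_net", np.linspace(6.0, 24.0, 10)), dtype=float)
    C_i = np.asarray(drivers.get("C_i", np.linspace(180.0, 340.0, A.size)), dtype=float)
    G, RL, gm = p["Gamma_star"], p["R_light"], p["g_mc"]
    C_c = C_i - A / gm
    if np.any(C_c <= G):
        raise ValueError("design implies C_c <= Gamma_star; increase C_i or g_mc")
    x = A + RL
    J_F = 4.0 * x * (C_c + 2.0 * G) / (C_c - G)  # Harley inversion
    A_noisy = A + rng.normal(0.0, sd, A.size)
    Q = np.full_like(A, 1500.0)
    calib = p.get("calib", 0.42)
    phi = J_F / (calib * Q)
    return pd.DataFrame({"A_net": A_noisy, "C_i": C_i, "J_F": J_F,
                         "Q": Q, "phi_PSII": phi})


def _make_pv(p, drivers, sd, rng):
    rwc = np.asarray(drivers.get("RWC", np.linspace(100.0, 76.0, 13)), dtype=float)
    pi_o, r_tlp = p["pi_o"], p["RWC_TLP"]
    # ideal symplastic dilution: pi = 100 pi_o / RWC; linear turgor to TLP
    pi = 100.0 * pi_o / rwc
    P = np.where(rwc > r_tlp, -pi_o * (rwc - r_tlp) / (100.0 - r_tlp), 0.0)
    psi = P + pi + rng.normal(0.0, sd, rwc.size)
    psi = np.minimum(psi, -1e-3)  # water potential stays negative
    return pd.DataFrame({"psi": psi, "RWC": rwc})


def _make_vuln(p, drivers, sd, rng):
    psi = np.asarray(drivers.get("psi", np.linspace(-0.5, -4.5, 9)), dtype=float)
    model = p.get("model", "sigmoidal")
    mp = {k: v for k, v in p.items() if k != "model"}
    plc = np.asarray(eval_vuln(model, mp, psi)) + rng.normal(0.0, sd, psi.size)
    plc = np.clip(plc, 0.0, 100.0)
    return pd.DataFrame({"psi": psi, "PLC": plc})


_MAKERS = {
    "aq": _make_aq,
    "aci": _make_aci,
    "t_response": _make_t_response,
    "gs": _make_gs,
    "r_light_kok": _make_r_light_kok,
    "r_light_yin": _make_r_light_yin,
    "r_light_walker_ort": _make_r_light_walker_ort,
    "gmc_variableJ": _make_gmc_variableJ,
    "pv": _make_pv,
    "vuln": _make_vuln,
}
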
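"""Physical constants and default biochemical parameter sets.

The default Rubisco/electron-transport kinetics are the *Nicotiana tabacum*
(tobacco) values of Bernacchi et al. (2001, Plant Cell Environ 24:253-259;
2003, Plant Cell Environ 26:1419-1430), the de-facto standard reference set
for C3 gas-exchange fitting.  Michaelis constants and the photorespiratory
CO2 compensation point (Gamma_star) scale with leaf temperature through
Arrhenius responses; their 25 degC values and activation energies are
transcribed below.

Units follow the package-wide canonical convention: temperatures in K,
CO2 mole fractions in umol mol-1 (K_o in mmol mol-1), rates in
umol m-2 s-1, energies in J mol-1.
"""

from __future__ import annotations

#: Universal gas constant, J mol-1 K-1.
R_GAS = 8.314

#: Reference temperature for all 25 degC parameter values, K.
T_REF = 298.15

#: Zero Celsius in Kelvin.
T0_KELVIN = 273.15

# --- Bernacchi tobacco kinetics (25 degC values + Arrhenius activation
#     energies, J mol-1).  K_c, K_o, Gamma_star from Bernacchi et al. 2001;
#     R_d scaling from Bernacchi et al. 2003. ---
BERNACCHI_KINETICS = {
    "K_c25": 404.9,        # umol mol-1
    "K_c_Ea": 79430.0,
    "K_o25": 278.4,        # mmol mol-1
    "K_o_Ea": 36380.0,
    "Gamma_star25": 42.75,  # umol mol-1
    "Gamma_star_Ea": 37830.0,
    "V_cmax_Ea": 65330.0,
    "J_max_Ea": 43540.0,
    "R_d_Ea": 46390.0,
}

#: Atmospheric O2 mole fraction, mmol mol-1.
O2_DEFAULT = 210.0

# Default leaf parameters for forward FvCB simulation (25 degC basis).
# Capacity values are representative of a well-fertilised tobacco leaf.
LEAF_DEFAULTS = {
    "V_cmax25": 100.0,     # umol m-2 s-1
    "J_max25": 180.0,      # umol m-2 s-1
    "V_TPU25": 12.0,       # umol m-2 s-1
    "R_d25": 1.5,          # umol m-2 s-1
    "Gamma_star25": BERNACCHI_KINETICS["Gamma_star25"],
    "K_c25": BERNACCHI_KINETICS["K_c25"],
    "K_o25": BERNACCHI_KINETICS["K_o25"],
    "phi_J": 0.3,          # mol e- mol-1 photons, apparent
    "theta_J": 0.85,       # dimensionless curvature
    "g_mc": 0.35,          # mol m-2 s-1 (mesophyll conductance to CO2)
    "V_cmax_Ea": BERNACCHI_KINETICS["V_cmax_Ea"],
    "J_max_Ea": BERNACCHI_KINETICS["J_max_Ea"],
    "R_d_Ea": BERNACCHI_KINETICS["R_d_Ea"],
    "K_c_Ea": BERNACCHI_KINETICS["K_c_Ea"],
    "K_o_Ea": BERNACCHI_KINETICS["K_o_Ea"],
    "Gamma_star_Ea": BERNACCHI_KINETICS["Gamma_star_Ea"],
}

# Default environmental drivers for forward simulation.
ENV_DEFAULTS = {
    "C_air": 420.0,        # umol mol-1
    "Q": 1500.0,           # umol m-2 s-1 PPFD
    "T_leaf": T_REF,       # K
    "O": O2_DEFAULT,       # mmol mol-1
    "g_tc": 0.15,          # mol m-2 s-1, total air-to-chloroplast CO2 conductance
}
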
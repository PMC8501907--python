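{
  "A_net": "PHOTO",
  "g_sw": "COND",
  "C_i": "Ci",
  "C_a": "CO2R",
  "C_s": "CO2S",
  "Q": "PARi",
  "T_leaf": "Tleaf",
  "T_air": "Tair",
  "RH": "RH_S",
  "D": "VpdL",
  "phi_PSII": "PhiPS2"
}
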
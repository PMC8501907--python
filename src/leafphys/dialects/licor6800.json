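{
  "A_net": "A",
  "g_sw": "gsw",
  "C_i": "Ci",
  "C_a": "Ca",
  "C_s": "Cs",
  "Q": "Qin",
  "T_leaf": "Tleaf",
  "T_air": "Tair",
  "RH": "RHcham",
  "D": "VPDleaf",
  "phi_PSII": "PhiPS2"
}
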
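{
  "notes": "In-vivo measured tumor transport and pharmacokinetic parameters for the carboxyfluorescein dye system. F_p is given as printed (0.047 mL/(mL s)); the package derives 0.046 from v_p/TT and accepts the printed value within its 10% consistency band. V_p_S (systemic mouse plasma volume from body weight) and VT (imaged tumor segment volume) are not part of the printed table; the packaged values are chosen so that the tumor:systemic plasma volume ratio is ~1:700.",
  "tumor_transport": {
    "v_p": 0.23,
    "v_e_av": 0.28,
    "TT": 5.0,
    "PS": 0.012,
    "F_p": 0.047,
    "Hct_mv": 0.19,
    "sd": {
      "v_p": 0.07,
      "v_e_av": 0.13,
      "TT": 0.5,
      "PS": 0.005,
      "F_p": 0.02
    }
  },
  "systemic_pk": {
    "V_D": 8.99,
    "V_p_S": 1.17,
    "k_p": 0.00129,
    "k_t": 0.0009,
    "k_e": 0.0008,
    "sd": {
      "V_D": 0.58,
      "k_p": 0.00052,
      "k_t": 0.00022,
      "k_e": 0.0003
    }
  },
  "geometry": {
    "VT": 0.00727
  }
}
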
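{
  "params": {
    "k1": 0.2,
    "k2": 0.2,
    "k3": 0.2,
    "k4": 0.06,
    "T_A": 300.0,
    "V_O2": 0.3
  },
  "shape": {
    "p": 2.0,
    "v": 0.5,
    "T_C_set": 310.15
  }
}
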
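{
  "c_A": 0.1,
  "c_B": 0.1,
  "w_A": 0.5,
  "w_B": 0.5,
  "q_A": 0.5,
  "q_B": 0.5,
  "d_A": 0.0,
  "d_B": 0.0,
  "p_B_given_A": 0.3,
  "p_A_given_B": 0.3,
  "variant": "standard",
  "lifestyle_A": "lytic",
  "lifestyle_B": "lytic",
  "se_A": false,
  "se_B": false
}
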
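{
  "a1": 1.400e5,
  "a2": -9.585e3,
  "a3": -1.976e3,
  "c2": 4.929e5,
  "c3": -2.981e5,
  "c4": 6.553e3,
  "beta1_deg": 0.790,
  "e2": 3.0146e4,
  "e3": -2.9556e4,
  "e4": -739.324,
  "beta2_deg": 90.100
}
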
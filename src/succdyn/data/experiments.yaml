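G1:
  G0: 0.03
  X0: 0.00105
  t_end: 60
G2:
  G0: 0.12
  X0: 0.00193
  t_end: 100
G3:
  G0: 0.24
  X0: 0.000725
  t_end: 100
G4:
  G0: 0.37
  X0: 0.00107
  t_end: 100
G5:
  G0: 0.45
  X0: 0.000564
  t_end: 100
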
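# Demo scenario: soy-lecithin-like mixed phospholipid sample, 8 mg.
composition:
  PC: 0.32
  PE: 0.16
  PG: 0.12
  SM: 0.09
  PA: 0.08
  LPA: 0.07
  LPI: 0.06
  LPC: 0.05
  UNK1: 0.03
  UNK2: 0.02
mass_mg: 8.0
age_hours: 0.0
noise_sigma: 0.65
seed: 20
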
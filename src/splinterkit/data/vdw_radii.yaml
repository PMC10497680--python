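# van der Waals radii (Å), Alvarez consensus set, with the Na+ override
# reduced from the published 2.50 Å to 1.50 Å so that sodium complexes sample
# the same effective contact range as other cations.
radii:
  H: 1.20
  He: 1.43
  Li: 2.12
  Be: 1.98
  B: 1.91
  C: 1.77
  N: 1.66
  O: 1.50
  F: 1.46
  Ne: 1.58
  Na: 2.50
  Mg: 2.51
  Al: 2.25
  Si: 2.19
  P: 1.90
  S: 1.89
  Cl: 1.82
  K: 2.73
  Ca: 2.62
  Br: 1.86
  I: 2.04
overrides:
  Na: 1.50
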
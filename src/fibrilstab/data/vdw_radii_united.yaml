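# United-atom van der Waals radii (Angstrom) by element.
# Hydrogens are not modelled; their volume is absorbed into the heavy-atom
# radii (Chothia-style united-atom convention). DEFAULT covers rare elements.
provenance: "united-atom element radii, Chothia (1976)-style convention"
radii:
  C: 1.90
  N: 1.70
  O: 1.40
  S: 1.80
  P: 1.90
  SE: 1.90
  DEFAULT: 1.80
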
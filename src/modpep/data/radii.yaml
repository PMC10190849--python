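# Van der Waals radii (Angstrom), element-keyed.
# Source: Bondi, J. Phys. Chem. 68 (1964) 441, as commonly used for
# Shrake-Rupley solvent accessibility (hydrogens listed for completeness;
# all analyses here run on heavy atoms only).
id: bondi64
radii:
  H: 1.20
  C: 1.70
  N: 1.55
  O: 1.52
  S: 1.80
  P: 1.80
  F: 1.47
default: 1.70
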
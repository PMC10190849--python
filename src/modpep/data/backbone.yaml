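# Ideal polypeptide backbone geometry used by the synthetic conformation
# builder. Bond lengths/angles are the Engh & Huber (1991) consensus values
# rounded to the precision routinely used by ideal-geometry builders.
bonds:      # Angstrom
  N_CA: 1.458
  CA_C: 1.525
  C_N: 1.329
  C_O: 1.231
angles:     # degrees
  N_CA_C: 111.2
  CA_C_N: 116.2
  C_N_CA: 121.7
  CA_C_O: 120.8
omega: 180.0
# Default (phi, psi) per backbone motif, degrees. The hairpin motif uses the
# strand values on both arms and the turn values on the two central residues
# (a type-I' like tight turn); tuned so that the two arms run antiparallel
# at a centre-to-centre spacing just outside hydrogen-bonding range, which
# is what the contact-planting machinery expects to start from.
motifs:
  helix:    {phi: -60.0, psi: -45.0}
  extended: {phi: -135.0, psi: 135.0}
  hairpin:
    strand: {phi: -135.0, psi: 135.0}
    turn:
      - {phi: -9.0, psi: -136.0}
      - {phi: -7.0, psi: -77.0}
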
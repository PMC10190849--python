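# Built-in registry of modular peptide-drug conjugate designs.
#
# Module convention (N -> C):
#   R1  targeting + tailoring segment (XIAP-binding AVPIAQK or the mutated
#       control MDEKAQK, followed by the caspase-3/7 substrate DEVD)
#   R2  optional insertion on the N-terminal side of the assembly motif
#   ASM the conserved amyloid-derived assembly motif KLVFFAE
#   R3  optional drug conjugated at the assembly-motif lysine side chain
#   R4  optional C-terminal extension / label
#
# Provenance: the published design table does not deposit full sequences;
# each entry below is a reconstruction from the modular description and the
# per-residue labels of the reported contact analysis, which pin the
# numbering of the Pbeta family (e.g. PRO3, GLU9, ASP11, LYS12, PHE16 all
# match AVPIAQKDEVD|KLVFFAE). Linker residues are a modelling choice and
# every record is overridable by a user file with the same schema.
designs:
  - name: Palpha
    description: alpha-helical scaffold with the mutated (non-targeting) R1
    segments:
      - {module: R1, sequence: MDEKAQKDEVD}
      - {module: ASM, sequence: KLVFFAE}
    ligands: []
    cleavage_motif: DEVD
    default_motif: helix

  - name: Pbeta
    description: beta-hairpin scaffold with the XIAP-targeting R1
    segments:
      - {module: R1, sequence: AVPIAQKDEVD}
      - {module: ASM, sequence: KLVFFAE}
    ligands: []
    cleavage_motif: DEVD
    default_motif: hairpin

  - name: Palpha_R4C
    description: Palpha with a CG extension and Cy dye on the added cysteine
    segments:
      - {module: R1, sequence: MDEKAQKDEVD}
      - {module: ASM, sequence: KLVFFAE}
      - {module: R4, sequence: CG}
    ligands:
      - {template: Cy, anchor: 19, site: side_chain, module: R4}
    cleavage_motif: DEVD
    default_motif: helix

  - name: Pbeta_R4C
    description: Pbeta with a CG extension and Cy dye on the added cysteine
    segments:
      - {module: R1, sequence: AVPIAQKDEVD}
      - {module: ASM, sequence: KLVFFAE}
      - {module: R4, sequence: CG}
    ligands:
      - {template: Cy, anchor: 19, site: side_chain, module: R4}
    cleavage_motif: DEVD
    default_motif: hairpin

  - name: Pbeta_R2C
    description: Pbeta with a GC insertion before the assembly motif, Cy on the cysteine
    segments:
      - {module: R1, sequence: AVPIAQKDEVD}
      - {module: R2, sequence: GC}
      - {module: ASM, sequence: KLVFFAE}
    ligands:
      - {template: Cy, anchor: 13, site: side_chain, module: R2}
    cleavage_motif: DEVD
    default_motif: hairpin

  - name: Pbeta_R4F
    description: Pbeta with FITC carried at the C terminus (R4)
    segments:
      - {module: R1, sequence: AVPIAQKDEVD}
      - {module: ASM, sequence: KLVFFAE}
    ligands:
      - {template: FITC, anchor: 18, site: C_term, module: R4}
    cleavage_motif: DEVD
    default_motif: hairpin

  - name: Pbeta_R4P
    description: Pbeta extended with the short peptide PDIFD at R4
    segments:
      - {module: R1, sequence: AVPIAQKDEVD}
      - {module: ASM, sequence: KLVFFAE}
      - {module: R4, sequence: PDIFD}
    ligands: []
    cleavage_motif: DEVD
    default_motif: hairpin

  - name: Pbeta_R4C_D
    description: Pbeta_R4C carrying pyrene as a demo drug on the assembly-motif lysine
    segments:
      - {module: R1, sequence: AVPIAQKDEVD}
      - {module: ASM, sequence: KLVFFAE}
      - {module: R4, sequence: CG}
    ligands:
      - {template: Cy, anchor: 19, site: side_chain, module: R4}
      - {template: Py, anchor: 12, site: side_chain, module: R3}
    cleavage_motif: DEVD
    default_motif: hairpin
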
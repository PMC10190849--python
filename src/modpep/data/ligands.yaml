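# Ligand templates for the conjugate registry.
#
# Chemistry is modelled only at the resolution the conformational analysis
# needs: elements, apolar flags, hydrogen-bond donor/acceptor flags and
# formal charge groups. No bond orders, no protonation equilibria. Local
# coordinates (Angstrom) are idealized planar/extended sketches used by the
# synthetic builder to place the ligand at its anchor; they are synthetic
# stand-ins, not crystallographic geometries.
#
# charge_group: atoms sharing a label form one formal charge unit with the
# given sign; salt bridges are counted between opposite-signed groups.
ligands:
  - name: Cy
    resname: CYD
    description: >
      Sulfonated cyanine dye (Cy5-like). Modelled as an apolar polymethine/
      indolenine core flanked by two anionic sulfonate groups whose oxygens
      are hydrogen-bond acceptors; the ring nitrogens are tertiary (neither
      donors nor acceptors). Exposes the acceptor and anionic surface a
      cyanine label presents to a peptide.
    attachment: C1
    atoms:
      - {name: C1,  element: C, xyz: [0.0, 0.0, 0.0],   apolar: true}
      - {name: C2,  element: C, xyz: [1.45, 0.60, 0.0], apolar: true}
      - {name: C3,  element: C, xyz: [2.90, 0.00, 0.0], apolar: true}
      - {name: C4,  element: C, xyz: [4.35, 0.60, 0.0], apolar: true}
      - {name: C5,  element: C, xyz: [5.80, 0.00, 0.0], apolar: true}
      - {name: C6,  element: C, xyz: [7.25, 0.60, 0.0], apolar: true}
      - {name: C7,  element: C, xyz: [8.70, 0.00, 0.0], apolar: true}
      - {name: N1,  element: N, xyz: [1.20, 1.95, 0.35]}
      - {name: N2,  element: N, xyz: [8.95, 1.95, 0.35]}
      - {name: S1,  element: S, xyz: [-0.90, 2.95, 0.80], charge_group: SO3A, charge: anionic}
      - {name: O1A, element: O, xyz: [-2.20, 2.55, 1.20], charge_group: SO3A, charge: anionic, acceptor: true}
      - {name: O1B, element: O, xyz: [-0.45, 3.95, 1.70], charge_group: SO3A, charge: anionic, acceptor: true}
      - {name: O1C, element: O, xyz: [-0.90, 3.45, -0.60], charge_group: SO3A, charge: anionic, acceptor: true}
      - {name: S2,  element: S, xyz: [10.25, 2.95, 0.80], charge_group: SO3B, charge: anionic}
      - {name: O2A, element: O, xyz: [11.55, 2.55, 1.20], charge_group: SO3B, charge: anionic, acceptor: true}
      - {name: O2B, element: O, xyz: [9.80, 3.95, 1.70], charge_group: SO3B, charge: anionic, acceptor: true}
      - {name: O2C, element: O, xyz: [10.25, 3.45, -0.60], charge_group: SO3B, charge: anionic, acceptor: true}
    bonds:
      - [C1, C2]
      - [C2, C3]
      - [C3, C4]
      - [C4, C5]
      - [C5, C6]
      - [C6, C7]
      - [C2, N1]
      - [C7, N2]
      - [N1, S1]
      - [N2, S2]
      - [S1, O1A]
      - [S1, O1B]
      - [S1, O1C]
      - [S2, O2A]
      - [S2, O2B]
      - [S2, O2C]

  - name: FITC
    resname: FIT
    description: >
      Fluorescein isothiocyanate, post-conjugation (thiourea linkage).
      Xanthene core carbons apolar, ring ether oxygen acceptor, phenolic
      hydroxyl donor/acceptor, benzoate carboxylate anionic.
    attachment: C1
    atoms:
      - {name: C1, element: C, xyz: [0.0, 0.0, 0.0]}
      - {name: S1, element: S, xyz: [0.30, -1.65, 0.0], apolar: true}
      - {name: N1, element: N, xyz: [1.15, 0.85, 0.0], donor: true}
      - {name: C2, element: C, xyz: [2.50, 0.35, 0.0], apolar: true}
      - {name: C3, element: C, xyz: [3.60, 1.25, 0.0], apolar: true}
      - {name: C4, element: C, xyz: [4.95, 0.80, 0.0], apolar: true}
      - {name: C5, element: C, xyz: [5.25, -0.60, 0.0], apolar: true}
      - {name: O1, element: O, xyz: [6.10, 1.70, 0.0], acceptor: true}
      - {name: C6, element: C, xyz: [7.45, 1.25, 0.0], apolar: true}
      - {name: C7, element: C, xyz: [8.55, 2.15, 0.0], apolar: true}
      - {name: O2, element: O, xyz: [9.85, 1.70, 0.0], donor: true, acceptor: true}
      - {name: C8, element: C, xyz: [4.20, -1.70, 0.3]}
      - {name: O3, element: O, xyz: [4.55, -2.95, 0.3], charge_group: CO2, charge: anionic, acceptor: true}
      - {name: O4, element: O, xyz: [2.95, -1.40, 0.6], charge_group: CO2, charge: anionic, acceptor: true}
    bonds:
      - [C1, S1]
      - [C1, N1]
      - [N1, C2]
      - [C2, C3]
      - [C3, C4]
      - [C4, C5]
      - [C4, O1]
      - [O1, C6]
      - [C6, C7]
      - [C7, O2]
      - [C5, C8]
      - [C8, O3]
      - [C8, O4]

  - name: Py
    resname: PYR
    description: >
      Pyrene, the hydrophobic demo drug. Sixteen fused aromatic carbons,
      all apolar; treated purely as an apolar contact surface (no pi-pi
      stacking model).
    attachment: C1
    atoms:
      - {name: C1, element: C, xyz: [-1.230, -0.710, 0.0], apolar: true}
      - {name: C2, element: C, xyz: [-1.230, 0.710, 0.0], apolar: true}
      - {name: C3, element: C, xyz: [0.000, 1.420, 0.0], apolar: true}
      - {name: C4, element: C, xyz: [0.000, -1.420, 0.0], apolar: true}
      - {name: C5, element: C, xyz: [1.230, 0.710, 0.0], apolar: true}
      - {name: C6, element: C, xyz: [1.230, -0.710, 0.0], apolar: true}
      - {name: C7, element: C, xyz: [2.459, 1.420, 0.0], apolar: true}
      - {name: C8, element: C, xyz: [2.459, -1.420, 0.0], apolar: true}
      - {name: C9, element: C, xyz: [0.000, 2.840, 0.0], apolar: true}
      - {name: C10, element: C, xyz: [0.000, -2.840, 0.0], apolar: true}
      - {name: C11, element: C, xyz: [-2.460, 1.420, 0.0], apolar: true}
      - {name: C12, element: C, xyz: [-2.460, -1.420, 0.0], apolar: true}
      - {name: C13, element: C, xyz: [2.459, -2.840, 0.0], apolar: true}
      - {name: C14, element: C, xyz: [2.459, 2.840, 0.0], apolar: true}
      - {name: C15, element: C, xyz: [3.689, -0.710, 0.0], apolar: true}
      - {name: C16, element: C, xyz: [3.689, 0.710, 0.0], apolar: true}
    bonds:
      - [C1, C2]
      - [C1, C4]
      - [C2, C3]
      - [C3, C5]
      - [C4, C6]
      - [C5, C6]
      - [C5, C7]
      - [C6, C8]
      - [C3, C9]
      - [C4, C10]
      - [C2, C11]
      - [C1, C12]
      - [C8, C13]
      - [C7, C14]
      - [C8, C15]
      - [C7, C16]
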
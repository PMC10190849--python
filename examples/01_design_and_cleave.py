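"""Designs and enzymatic cleavage.

Loads two built-in conjugate designs, shows their module partition, and
applies the caspase-3/7 cleavage rule (cut C-terminal to the DEVD motif's
last aspartate).  The product carrying the KLVFFAE assembly motif is the
species that self-assembles after activation.
"""
import modpep as mp

for name in ("Pbeta", "Pbeta_R4C"):
    topo = mp.load_design(name)
    print(f"{name}: {topo.sequence}")
    for span in topo.spans:
        if span.start is not None:
            seg = topo.sequence[span.start - 1:span.end]
            print(f"  {span.module_id:>3}: residues {span.start}-{span.end} ({seg})"
                  + (f" + {', '.join(span.ligands)}" if span.ligands else ""))
        else:
            print(f"  {span.module_id:>3}: ligand(s) {', '.join(span.ligands)}")
    for product in mp.cleave(topo):
        ligs = ", ".join(l.label for l in product.ligands) or "none"
        print(f"  product {product.name}: {product.sequence} (ligands: {ligs})")
    print()

# The assembly-motif lysine of Pbeta sits at position 12:
topo = mp.load_design("Pbeta")
print("module of residue 12:", mp.module_of(topo, 12))
# -> ASM: the drug-conjugation site lives on the conserved assembly motif.
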
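"""Reference contact fixtures (synthetic).

Idealized single conformations that reproduce, by construction, the
canonical interaction pattern reported for the Pbeta and Pbeta_R4C
designs:

* Pbeta — four hydrogen bonds (PHE16:PRO3, VAL14:ALA5, LYS7:LYS12,
  ALA5:VAL14) and two salt bridges (LYS12:ASP11, LYS7:GLU9);
* Pbeta_R4C — six inter-module hydrogen bonds (Cy:ASP11, LYS12:Cy,
  ALA17:VAL2, ALA1:Cy, GLN6:VAL14, ILE4:PHE15), three inter-module salt
  bridges (LYS12:Cy, LYS12:ASP11, ALA1:Cy) and one intra-module salt
  bridge (LYS7:GLU9).

Both start from an ideal beta-hairpin (turn at residues 9-10, which places
each listed partner pair on opposite strands) and plant each contact at a
geometry satisfying the default detector criteria: hydrogen bonds at
2.9-3.2 A, salt bridges that are *only* salt bridges at 3.7 A (outside the
3.5 A hydrogen-bond cutoff), and the LYS12:Cy / ALA1:Cy pairs at 3.2 A so
that — as reported — they register as both hydrogen bond and salt bridge.
These are synthetic stand-ins for unavailable relaxation snapshots; plants
may locally distort covalent geometry.
"""
from __future__ import annotations

from functools import lru_cache

from .interactions import ContactCriteria
from .conjugate import load_design
from .structure import Conformation
from .synthetic import BackboneRecipe, PlantedContact, build_backbone, plant_contacts

PBETA_PLANTS = [
    PlantedContact("hbond", 16, "N", 3, "O", 2.9),      # PHE16:PRO3
    PlantedContact("hbond", 14, "N", 5, "O", 2.9),      # VAL14:ALA5
    PlantedContact("hbond", 7, "N", 12, "O", 2.9),      # LYS7:LYS12
    PlantedContact("hbond", 5, "N", 14, "O", 2.9),      # ALA5:VAL14
    PlantedContact("saltbridge", 12, "NZ", 11, "OD1", 3.7),   # LYS12:ASP11
    PlantedContact("saltbridge", 7, "NZ", 9, "OE1", 3.7),     # LYS7:GLU9
]

PBETA_R4C_PLANTS = [
    PlantedContact("hbond", 11, "N", "Cy", "O2B", 3.2),       # Cy:ASP11
    PlantedContact("hbond", 12, "NZ", "Cy", "O2A", 3.2),      # LYS12:Cy
    PlantedContact("saltbridge", 12, "NZ", "Cy", "O2A", 3.2),
    PlantedContact("hbond", 17, "N", 2, "O", 2.9),            # ALA17:VAL2
    PlantedContact("hbond", 1, "N", "Cy", "O1B", 3.2),        # ALA1:Cy
    PlantedContact("saltbridge", 1, "N", "Cy", "O1B", 3.2),
    PlantedContact("hbond", 6, "NE2", 14, "O", 2.9),          # GLN6:VAL14
    PlantedContact("hbond", 4, "N", 15, "O", 2.9),            # ILE4:PHE15
    PlantedContact("saltbridge", 12, "NZ", 11, "OD1", 3.7),   # LYS12:ASP11
    PlantedContact("saltbridge", 7, "NZ", 9, "OE1", 3.7),     # LYS7:GLU9
]


@lru_cache(maxsize=4)
def pbeta_contact_fixture(criteria: ContactCriteria = ContactCriteria()
                          ) -> Conformation:
    """Hairpin Pbeta conformation with its canonical contact set planted.

    Cached: callers share one instance and must not mutate it."""
    topo = load_design("Pbeta")
    recipe = BackboneRecipe(topology=topo, motif="hairpin", turn_residues=(9, 10))
    conf = build_backbone(recipe)
    return plant_contacts(conf, PBETA_PLANTS, criteria)


@lru_cache(maxsize=4)
def pbeta_r4c_contact_fixture(criteria: ContactCriteria = ContactCriteria()
                              ) -> Conformation:
    """Hairpin Pbeta_R4C conformation with its canonical inter/intra-module
    contact set planted (Cy sulfonate groups reach the N-terminal and
    turn-end regions)."""
    topo = load_design("Pbeta_R4C")
    recipe = BackboneRecipe(topology=topo, motif="hairpin", turn_residues=(9, 10))
    conf = build_backbone(recipe)
    return plant_contacts(conf, PBETA_R4C_PLANTS, criteria)
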
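"""Per-atom chemistry: elements, van-der-Waals radii, polarity and charge flags.

Everything downstream (SASA, contact detectors) consumes flat per-atom flags:

* ``apolar`` — carbon or sulfur with no covalent N/O neighbour; these atoms
  carry hydrophobic contacts.
* ``donor`` / ``acceptor`` — heavy-atom hydrogen-bond capability.  Structures
  are hydrogen-free, so donors are N/O atoms that bear at least one hydrogen
  in the parent amino acid (backbone amide N except proline, Lys NZ, Ser OG,
  ...), and acceptors are all oxygens plus non-protonated nitrogens.
* ``charge_group`` / ``charge_sign`` — formal charge units for salt-bridge
  detection: Lys/Arg side chains and the free N terminus are cationic;
  Asp/Glu side chains, the free C terminus and ligand sulfonate/carboxylate
  groups are anionic.  Conjugation neutralises the anchor: a ligand on a Lys
  side chain consumes the NZ amine, a C-terminal ligand consumes the
  terminal carboxylate.

Residue heavy-atom templates (names, bonds, ideal side-chain coordinates at
a default rotamer) are derived once per process from seeded RDKit ETKDG
embeddings of single amino acids, which keeps the builder free of a
hand-curated rotamer library while remaining deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import yaml

from . import _data
from .conjugate import ConjugateTopology, THREE_LETTER

BACKBONE_NAMES = ("N", "CA", "C", "O")

_SIDECHAIN_ANCHOR = {"K": "NZ", "C": "SG", "S": "OG", "T": "OG1", "Y": "OH"}

_CATIONIC_SIDECHAIN = {"K": ("NZ",), "R": ("NE", "NH1", "NH2")}
_ANIONIC_SIDECHAIN = {"D": ("OD1", "OD2"), "E": ("OE1", "OE2")}


@lru_cache(maxsize=None)
def radii_table(table_id: str = "bondi64") -> tuple[dict, float]:
    raw = yaml.safe_load(_data.read_text("radii.yaml"))
    if raw["id"] != table_id:
        raise ValueError(f"unknown radii table {table_id!r}")
    return dict(raw["radii"]), float(raw["default"])


def vdw_radius(element: str, table_id: str = "bondi64") -> float:
    radii, default = radii_table(table_id)
    return radii.get(element.capitalize(), default)


@dataclass(frozen=True)
class Atom:
    """One heavy atom of a conformation (metadata only; coordinates live
    in the owning Conformation's coordinate array)."""
    serial: int
    name: str
    element: str
    residue_index: int | None          # None for ligand atoms
    ligand: str | None                 # ligand instance label, or None
    parent_label: str                  # e.g. "LYS12" or "Cy"
    radius: float
    apolar: bool = False
    donor: bool = False
    acceptor: bool = False
    charge_sign: str | None = None
    charge_group: str | None = None

    @property
    def parent(self) -> str:
        """Unique parent key: ligand label or residue index as string."""
        return self.ligand if self.ligand is not None else str(self.residue_index)


# ---------------------------------------------------------------------------
# Residue templates (RDKit, seeded, cached)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueTemplate:
    code: str
    atom_names: tuple[str, ...]            # chain atoms: backbone + side chain, no OXT
    elements: dict
    coords: dict                           # name -> np.ndarray(3,)
    bonds: tuple[tuple[str, str], ...]     # heavy-atom bonds incl. OXT-free
    h_counts: dict                         # name -> number of attached hydrogens
    apolar: dict                           # name -> bool


@lru_cache(maxsize=None)
def residue_template(code: str) -> ResidueTemplate:
    from rdkit import Chem
    from rdkit.Chem import AllChem

    if code not in THREE_LETTER:
        raise ValueError(f"unknown residue code {code!r}")
    mol = Chem.MolFromSequence(code)
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = 74207281
    if AllChem.EmbedMolecule(molh, params) < 0:   # pragma: no cover
        params.randomSeed = 74207282
        if AllChem.EmbedMolecule(molh, params) < 0:
            raise RuntimeError(f"embedding failed for residue {code}")
    AllChem.MMFFOptimizeMolecule(molh)
    mol = Chem.RemoveHs(molh)
    conf = mol.GetConformer()

    names, elements, coords, h_counts = [], {}, {}, {}
    for atom in mol.GetAtoms():
        info = atom.GetPDBResidueInfo()
        name = info.GetName().strip()
        names.append(name)
        elements[name] = atom.GetSymbol()
        coords[name] = np.array(conf.GetAtomPosition(atom.GetIdx()))
        h_counts[name] = atom.GetTotalNumHs()
    bonds = []
    idx2name = {a.GetIdx(): a.GetPDBResidueInfo().GetName().strip()
                for a in mol.GetAtoms()}
    for b in mol.GetBonds():
        bonds.append((idx2name[b.GetBeginAtomIdx()], idx2name[b.GetEndAtomIdx()]))
    neighbours = {n: set() for n in names}
    for a, b in bonds:
        neighbours[a].add(b)
        neighbours[b].add(a)
    apolar = {
        n: elements[n] in ("C", "S")
        and not any(elements[m] in ("N", "O") for m in neighbours[n])
        for n in names
    }
    chain_atoms = tuple(n for n in names if n != "OXT")
    return ResidueTemplate(
        code=code, atom_names=chain_atoms, elements=elements, coords=coords,
        bonds=tuple(bonds), h_counts=h_counts, apolar=apolar)


def sidechain_atom_names(code: str) -> tuple[str, ...]:
    tpl = residue_template(code)
    return tuple(n for n in tpl.atom_names if n not in BACKBONE_NAMES)


def sidechain_anchor_atom(code: str) -> str:
    """Atom name used as covalent anchor for side-chain ligand conjugation."""
    if code in _SIDECHAIN_ANCHOR:
        return _SIDECHAIN_ANCHOR[code]
    side = sidechain_atom_names(code)
    return side[-1] if side else "CA"


# ---------------------------------------------------------------------------
# Atom list for a topology
# ---------------------------------------------------------------------------

def topology_atoms(topology: ConjugateTopology,
                   radii_table_id: str = "bondi64") -> tuple[Atom, ...]:
    """The canonical heavy-atom list for a topology, flags assigned.

    Order: residues N->C (backbone N, CA, C, O then side chain, template
    order), then ligands in attachment order.  This is the order every
    Conformation bound to the topology must follow.
    """
    # conjugation neutralises the anchor's charge/donor capability
    sidechain_conj = {(l.anchor, sidechain_anchor_atom(
        topology.residues[l.anchor - 1].code))
        for l in topology.ligands if l.site == "side_chain"}
    cterm_conj = {l.anchor for l in topology.ligands if l.site == "C_term"}
    nterm_conj = {l.anchor for l in topology.ligands if l.site == "N_term"}

    atoms: list[Atom] = []
    serial = 1
    for res in topology.residues:
        tpl = residue_template(res.code)
        label = res.label
        for name in tpl.atom_names:
            element = tpl.elements[name]
            apolar = tpl.apolar[name]
            donor = acceptor = False
            sign = group = None
            if name == "N":
                donor = res.code != "P"
                if res.is_N_terminal:
                    donor = True
                    if res.index not in nterm_conj:
                        sign, group = "cationic", f"res{res.index}:NTER"
            elif name == "O":
                acceptor = True
                if res.is_C_terminal and res.index not in cterm_conj:
                    sign, group = "anionic", f"res{res.index}:CTER"
            elif name not in BACKBONE_NAMES:
                if element in ("N", "O"):
                    donor = tpl.h_counts[name] > 0
                    acceptor = element == "O" or tpl.h_counts[name] == 0
                if name in _CATIONIC_SIDECHAIN.get(res.code, ()):
                    sign, group = "cationic", f"res{res.index}:+"
                elif name in _ANIONIC_SIDECHAIN.get(res.code, ()):
                    # deprotonated carboxylate in chain context: acceptor only
                    sign, group = "anionic", f"res{res.index}:-"
                    donor = False
                if (res.index, name) in sidechain_conj:
                    donor = False
                    sign = group = None
            atoms.append(Atom(
                serial=serial, name=name, element=element,
                residue_index=res.index, ligand=None, parent_label=label,
                radius=vdw_radius(element, radii_table_id),
                apolar=apolar, donor=donor, acceptor=acceptor,
                charge_sign=sign, charge_group=group))
            serial += 1

    for lig in topology.ligands:
        for la in lig.template.atoms:
            group = f"lig:{lig.label}:{la.charge_group}" if la.charge_group else None
            atoms.append(Atom(
                serial=serial, name=la.name, element=la.element,
                residue_index=None, ligand=lig.label, parent_label=lig.label,
                radius=vdw_radius(la.element, radii_table_id),
                apolar=la.apolar, donor=la.donor, acceptor=la.acceptor,
                charge_sign=la.charge_sign, charge_group=group))
            serial += 1
    return tuple(atoms)
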
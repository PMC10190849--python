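"""Conformations and ensembles bound to a conjugate topology.

A :class:`Conformation` is one coordinate frame over the canonical atom
list of a topology (see :func:`modpep.chemistry.topology_atoms`); an
:class:`Ensemble` is an ordered stack of frames sharing one topology and
atom metadata.  Ensembles are exchanged as standard multi-model PDB text
(peptide atoms as ATOM, ligand groups as HETATM with their registered
3-letter codes), read and written through gemmi.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

from .chemistry import Atom, topology_atoms
from .conjugate import ConjugateTopology, THREE_LETTER


class StructureError(ValueError):
    """Raised for atom/topology mismatches and malformed coordinate input."""


@dataclass
class Conformation:
    topology: ConjugateTopology
    atoms: tuple[Atom, ...]
    coords: np.ndarray                 # (n_atoms, 3), Angstrom
    frame_index: int = 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise StructureError(
                f"coordinate shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_indices(self, predicate) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if predicate(a)],
                        dtype=int)

    def module_indices(self, module_ids) -> np.ndarray:
        """Indices of atoms belonging to any of the given module ids."""
        if isinstance(module_ids, str):
            module_ids = {module_ids}
        module_ids = set(module_ids)
        topo = self.topology
        return self.atom_indices(lambda a: topo.module_of(a) in module_ids)

    def subset(self, indices: np.ndarray) -> "Conformation":
        """A conformation over a subset of atoms at identical coordinates.

        Keeps the parent topology reference; used for occlusion baselines
        (e.g. the assembly module in isolation)."""
        indices = np.asarray(indices, dtype=int)
        return Conformation(
            topology=self.topology,
            atoms=tuple(self.atoms[i] for i in indices),
            coords=self.coords[indices],
            frame_index=self.frame_index)


@dataclass
class Ensemble:
    topology: ConjugateTopology
    frames: list[Conformation]
    frame_spacing: float = 1.0         # arbitrary units between frames

    def __post_init__(self):
        if not self.frames:
            raise StructureError("ensemble must contain at least one frame")
        n = self.frames[0].n_atoms
        for f in self.frames:
            if f.n_atoms != n:
                raise StructureError("inconsistent atom count across frames")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def atoms(self) -> tuple[Atom, ...]:
        return self.frames[0].atoms

    def coords_stack(self) -> np.ndarray:
        return np.stack([f.coords for f in self.frames])

    @classmethod
    def from_coords(cls, topology: ConjugateTopology, coords: np.ndarray,
                    atoms: tuple[Atom, ...] | None = None,
                    frame_spacing: float = 1.0) -> "Ensemble":
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        if atoms is None:
            atoms = topology_atoms(topology)
        frames = [Conformation(topology, atoms, c, frame_index=i)
                  for i, c in enumerate(coords)]
        return cls(topology=topology, frames=frames, frame_spacing=frame_spacing)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _ligand_seqids(topology: ConjugateTopology) -> dict[str, int]:
    base = topology.n_residues
    return {lig.label: base + k for k, lig in enumerate(topology.ligands, start=1)}


def write_ensemble(ensemble: Ensemble) -> str:
    """Render an ensemble as multi-model PDB text (one MODEL per frame)."""
    topology = ensemble.topology
    lig_seqids = _ligand_seqids(topology)
    lig_resnames = {l.label: l.template.resname for l in topology.ligands}

    st = gemmi.Structure()
    st.name = topology.name
    for fi, frame in enumerate(ensemble.frames, start=1):
        model = gemmi.Model(fi)
        chain = gemmi.Chain("A")
        current = None
        residue = None
        for atom, pos in zip(frame.atoms, frame.coords):
            if atom.ligand is None:
                key = ("res", atom.residue_index)
                resname = THREE_LETTER[topology.residues[atom.residue_index - 1].code]
                seqid, het = atom.residue_index, "A"
            else:
                key = ("lig", atom.ligand)
                resname = lig_resnames[atom.ligand]
                seqid, het = lig_seqids[atom.ligand], "H"
            if key != current:
                residue = gemmi.Residue()
                residue.name = resname
                residue.seqid = gemmi.SeqId(seqid, " ")
                residue.het_flag = het
                chain.add_residue(residue)
                current = key
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.serial = atom.serial
            ga.pos = gemmi.Position(*pos)
            chain[-1].add_atom(ga)
        model.add_chain(chain)
        st.add_model(model)
    text = st.make_pdb_string()
    if ensemble.n_frames == 1 and "MODEL " not in text:
        # gemmi collapses single-model output; keep the MODEL/ENDMDL frame
        lines = text.splitlines()
        first = next(i for i, l in enumerate(lines)
                     if l.startswith(("ATOM", "HETATM")))
        last = max(i for i, l in enumerate(lines)
                   if l.startswith(("ATOM", "HETATM", "TER")))
        lines.insert(last + 1, "ENDMDL")
        lines.insert(first, "MODEL        1")
        text = "\n".join(lines) + "\n"
    return text


def read_ensemble(pdb_text: str, topology: ConjugateTopology,
                  radii_table_id: str = "bondi64",
                  frame_spacing: float = 1.0) -> Ensemble:
    """Parse multi-model PDB text and bind it to a topology.

    Every model must contain exactly the topology's canonical atoms,
    matched by (residue number, residue name, atom name); HETATM residue
    names must correspond to registered ligand templates of the topology.
    The first mismatch is reported by name.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise StructureError("PDB text contains no models")
    atoms = topology_atoms(topology, radii_table_id)
    lig_seqids = _ligand_seqids(topology)
    lig_resnames = {l.label: l.template.resname for l in topology.ligands}
    known_resnames = set(THREE_LETTER.values()) | set(lig_resnames.values())

    expected_keys = []
    for atom in atoms:
        if atom.ligand is None:
            resname = THREE_LETTER[topology.residues[atom.residue_index - 1].code]
            expected_keys.append((atom.residue_index, resname, atom.name))
        else:
            expected_keys.append(
                (lig_seqids[atom.ligand], lig_resnames[atom.ligand], atom.name))

    frames = []
    for mi, model in enumerate(st):
        found: dict[tuple, np.ndarray] = {}
        count = 0
        for chain in model:
            for res in chain:
                for a in res:
                    if res.name not in known_resnames:
                        raise StructureError(
                            f"model {mi + 1}: residue {res.name} {res.seqid.num} "
                            f"is not part of topology {topology.name}")
                    found[(res.seqid.num, res.name, a.name)] = \
                        np.array([a.pos.x, a.pos.y, a.pos.z])
                    count += 1
        coords = np.empty((len(atoms), 3))
        for i, key in enumerate(expected_keys):
            if key not in found:
                raise StructureError(
                    f"model {mi + 1}: missing atom {key[2]} of {key[1]} {key[0]}")
            coords[i] = found[key]
        if count != len(atoms):
            extras = set(found) - set(expected_keys)
            name = sorted(extras)[0] if extras else "?"
            raise StructureError(
                f"model {mi + 1}: {count} atoms found, {len(atoms)} expected "
                f"(first unexpected: {name})")
        frames.append(Conformation(topology, atoms, coords, frame_index=mi))
    return Ensemble(topology=topology, frames=frames, frame_spacing=frame_spacing)


def write_frame_series_csv(path, **series) -> pd.DataFrame:
    """Write named per-frame scalar series (RMSD, RGYR, counts, ...) to CSV."""
    df = pd.DataFrame(dict(series))
    df.insert(0, "frame", np.arange(len(df)))
    df.to_csv(path, index=False, float_format="%.6f")
    return df
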
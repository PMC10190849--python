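"""Non-covalent interaction detection and module-pair landscapes.

Three contact kinds are detected on hydrogen-free heavy-atom structures:

* hydrogen bond — donor/acceptor heavy-atom distance <= 3.5 A (distance-only
  criterion, since structures carry no hydrogens; a donor-hydrogen-acceptor
  angle test would apply only when hydrogens are present);
* salt bridge — minimum distance between atoms of a cationic and an anionic
  formal charge group <= 4.0 A, counted per charge-group pair;
* hydrophobic — apolar-atom pairs within 5.0 A; the reported quantity is the
  number of distinct apolar atoms participating in at least one
  cross-partition pair, not the number of pairs.

Cutoffs are configurable conventions (none are fixed by the underlying
assay).  Trivial covalent neighbours are excluded: intra-parent pairs, the
amide N(i+1)..O(i) pair of sequence-adjacent residues, and pairs between a
ligand and its own anchor residue.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .conjugate import ConjugateTopology, MODULE_IDS
from .structure import Conformation, Ensemble


@dataclass(frozen=True)
class ContactCriteria:
    hbond_distance: float = 3.5        # donor-acceptor heavy-atom cutoff, A
    hbond_angle: float = 130.0         # D-H...A minimum, used only with hydrogens
    saltbridge_distance: float = 4.0   # closest approach of charge groups, A
    hydrophobic_distance: float = 5.0  # apolar pair cutoff, A


@dataclass(frozen=True)
class Partner:
    label: str                         # residue label (LYS12) or ligand label (Cy)
    module: str
    atom: str | None = None
    serial: int | None = None


@dataclass(frozen=True)
class ContactRecord:
    kind: str                          # hbond | saltbridge | hydrophobic
    a: Partner
    b: Partner
    distance: float
    angle: float | None = None
    frame: int = 0

    @property
    def pair_key(self) -> tuple:
        """Canonical partner-level identity (order-free)."""
        return (self.kind,) + tuple(sorted((self.a.label, self.b.label)))

    @property
    def module_pair(self) -> tuple:
        return _canonical_pair(self.a.module, self.b.module)


def _canonical_pair(m1: str, m2: str) -> tuple:
    order = {m: i for i, m in enumerate(MODULE_IDS)}
    return (m1, m2) if order[m1] <= order[m2] else (m2, m1)


def _anchor_pairs(topology: ConjugateTopology) -> set:
    return {(l.label, l.anchor) for l in topology.ligands}


def _excluded(a, b, anchor_pairs) -> bool:
    """Trivial covalent-neighbour exclusions (see module docstring)."""
    if a.parent == b.parent:
        return True
    if a.ligand is not None and (a.ligand, b.residue_index) in anchor_pairs:
        return True
    if b.ligand is not None and (b.ligand, a.residue_index) in anchor_pairs:
        return True
    return False


def _adjacent_backbone_amide(donor, acceptor) -> bool:
    return (donor.ligand is None and acceptor.ligand is None
            and donor.name == "N" and acceptor.name == "O"
            and donor.residue_index == acceptor.residue_index + 1)


def _sequence_adjacent(a, b) -> bool:
    return (a.ligand is None and b.ligand is None
            and abs(a.residue_index - b.residue_index) == 1)


def _partner(conformation, i) -> Partner:
    atom = conformation.atoms[i]
    return Partner(label=atom.parent_label,
                   module=conformation.topology.module_of(atom),
                   atom=atom.name, serial=atom.serial)


def detect_hbonds(conformation: Conformation,
                  criteria: ContactCriteria = ContactCriteria()
                  ) -> list[ContactRecord]:
    """One record per donor-atom/acceptor-atom pair within the cutoff."""
    anchor_pairs = _anchor_pairs(conformation.topology)
    donors = conformation.atom_indices(lambda a: a.donor)
    acceptors = conformation.atom_indices(lambda a: a.acceptor)
    records = []
    if len(donors) == 0 or len(acceptors) == 0:
        return records
    atree = cKDTree(conformation.coords[acceptors])
    for di in donors:
        d = conformation.atoms[di]
        for k in atree.query_ball_point(conformation.coords[di],
                                        criteria.hbond_distance):
            ai = acceptors[k]
            if ai == di:
                continue
            a = conformation.atoms[ai]
            if _excluded(d, a, anchor_pairs) or _adjacent_backbone_amide(d, a):
                continue
            dist = float(np.linalg.norm(
                conformation.coords[di] - conformation.coords[ai]))
            records.append(ContactRecord(
                kind="hbond", a=_partner(conformation, di),
                b=_partner(conformation, ai), distance=dist,
                frame=conformation.frame_index))
    return records


def detect_salt_bridges(conformation: Conformation,
                        criteria: ContactCriteria = ContactCriteria()
                        ) -> list[ContactRecord]:
    """One record per (cationic group, anionic group) within closest-approach
    distance."""
    anchor_pairs = _anchor_pairs(conformation.topology)
    groups: dict[str, list[int]] = defaultdict(list)
    for i, atom in enumerate(conformation.atoms):
        if atom.charge_group:
            groups[atom.charge_group].append(i)
    cationic = {g: idx for g, idx in groups.items()
                if conformation.atoms[idx[0]].charge_sign == "cationic"}
    anionic = {g: idx for g, idx in groups.items()
               if conformation.atoms[idx[0]].charge_sign == "anionic"}
    records = []
    for gp, pidx in cationic.items():
        for gn, nidx in anionic.items():
            ap, an = conformation.atoms[pidx[0]], conformation.atoms[nidx[0]]
            if _excluded(ap, an, anchor_pairs):
                continue
            diff = conformation.coords[pidx][:, None, :] - conformation.coords[nidx][None, :, :]
            d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
            k = np.unravel_index(np.argmin(d), d.shape)
            if d[k] <= criteria.saltbridge_distance:
                records.append(ContactRecord(
                    kind="saltbridge",
                    a=_partner(conformation, pidx[k[0]]),
                    b=_partner(conformation, nidx[k[1]]),
                    distance=float(d[k]),
                    frame=conformation.frame_index))
    return records


def hydrophobic_contact_atoms(conformation: Conformation,
                              partition_a, partition_b,
                              criteria: ContactCriteria = ContactCriteria()
                              ) -> tuple[int, set, list[ContactRecord]]:
    """Distinct apolar atoms engaged across two module partitions.

    Returns (atom count, set of atom serials, one record per parent pair at
    its closest approach).  ``partition_a``/``partition_b`` are module ids or
    sets of module ids; for identical partitions, intra-parent and
    sequence-adjacent pairs are excluded.
    """
    anchor_pairs = _anchor_pairs(conformation.topology)
    topo = conformation.topology
    if isinstance(partition_a, str):
        partition_a = {partition_a}
    if isinstance(partition_b, str):
        partition_b = {partition_b}
    ia = conformation.atom_indices(
        lambda a: a.apolar and topo.module_of(a) in set(partition_a))
    ib = conformation.atom_indices(
        lambda a: a.apolar and topo.module_of(a) in set(partition_b))
    engaged: set[int] = set()
    closest: dict[tuple, tuple] = {}
    if len(ia) and len(ib):
        tb = cKDTree(conformation.coords[ib])
        for i in ia:
            a = conformation.atoms[i]
            for k in tb.query_ball_point(conformation.coords[i],
                                         criteria.hydrophobic_distance):
                j = ib[k]
                if j == i:
                    continue
                b = conformation.atoms[j]
                if (_excluded(a, b, anchor_pairs) or _sequence_adjacent(a, b)):
                    continue
                dist = float(np.linalg.norm(
                    conformation.coords[i] - conformation.coords[j]))
                engaged.add(a.serial)
                engaged.add(b.serial)
                key = tuple(sorted((a.parent_label, b.parent_label)))
                if key not in closest or dist < closest[key][0]:
                    closest[key] = (dist, i, j)
    records = [
        ContactRecord(kind="hydrophobic", a=_partner(conformation, i),
                      b=_partner(conformation, j), distance=dist,
                      frame=conformation.frame_index)
        for dist, i, j in closest.values()
    ]
    return len(engaged), engaged, records


# ---------------------------------------------------------------------------
# Landscapes over ensembles
# ---------------------------------------------------------------------------

@dataclass
class InteractionLandscape:
    """Module-pair aggregated interaction statistics over an ensemble."""
    n_frames: int
    hbond_mean: dict                   # (m1, m2) -> mean count per frame
    saltbridge_mean: dict
    hydrophobic_mean_atoms: dict       # (m1, m2) -> mean engaged-atom count
    occupancy: dict                    # contact pair_key -> fraction of frames
    per_frame_hbonds: list = field(repr=False, default_factory=list)
    per_frame_saltbridges: list = field(repr=False, default_factory=list)

    def mean_total(self, kind: str, inter: bool | None = None) -> float:
        source = {"hbond": self.hbond_mean,
                  "saltbridge": self.saltbridge_mean,
                  "hydrophobic": self.hydrophobic_mean_atoms}[kind]
        total = 0.0
        for (m1, m2), v in source.items():
            if inter is None or (m1 != m2) == inter:
                total += v
        return total

    def to_frame(self) -> pd.DataFrame:
        pairs = sorted(set(self.hbond_mean) | set(self.saltbridge_mean)
                       | set(self.hydrophobic_mean_atoms))
        rows = [{
            "module_a": m1, "module_b": m2,
            "hbond_mean": self.hbond_mean.get((m1, m2), 0.0),
            "saltbridge_mean": self.saltbridge_mean.get((m1, m2), 0.0),
            "hydrophobic_mean_atoms": self.hydrophobic_mean_atoms.get((m1, m2), 0.0),
        } for m1, m2 in pairs]
        return pd.DataFrame(rows)

    def occupancy_frame(self) -> pd.DataFrame:
        rows = [{"kind": k[0], "partner_a": k[1], "partner_b": k[2],
                 "occupancy": v}
                for k, v in sorted(self.occupancy.items())]
        return pd.DataFrame(rows, columns=["kind", "partner_a", "partner_b",
                                           "occupancy"])


def _present_modules(topology: ConjugateTopology) -> list[str]:
    return [s.module_id for s in topology.spans]


def landscape(ensemble: Ensemble, topology: ConjugateTopology | None = None,
              criteria: ContactCriteria = ContactCriteria()
              ) -> InteractionLandscape:
    """Aggregate contacts over frames into per-module-pair means and
    per-contact occupancies."""
    if topology is None:
        topology = ensemble.topology
    modules = _present_modules(topology)
    pairs = [_canonical_pair(m1, m2)
             for i, m1 in enumerate(modules) for m2 in modules[i:]]
    hb_counts = {p: [] for p in pairs}
    sb_counts = {p: [] for p in pairs}
    hp_counts = {p: [] for p in pairs}
    presence: dict[tuple, int] = defaultdict(int)
    per_frame_hb, per_frame_sb = [], []

    for frame in ensemble.frames:
        hb = detect_hbonds(frame, criteria)
        sb = detect_salt_bridges(frame, criteria)
        per_frame_hb.append(hb)
        per_frame_sb.append(sb)
        for p in pairs:
            hb_counts[p].append(sum(1 for r in hb if r.module_pair == p))
            sb_counts[p].append(sum(1 for r in sb if r.module_pair == p))
            n_atoms, _, _ = hydrophobic_contact_atoms(frame, {p[0]}, {p[1]}, criteria)
            hp_counts[p].append(n_atoms)
        for key in {r.pair_key for r in hb} | {r.pair_key for r in sb}:
            presence[key] += 1

    n = ensemble.n_frames
    return InteractionLandscape(
        n_frames=n,
        hbond_mean={p: float(np.mean(v)) for p, v in hb_counts.items()},
        saltbridge_mean={p: float(np.mean(v)) for p, v in sb_counts.items()},
        hydrophobic_mean_atoms={p: float(np.mean(v)) for p, v in hp_counts.items()},
        occupancy={k: c / n for k, c in presence.items()},
        per_frame_hbonds=per_frame_hb,
        per_frame_saltbridges=per_frame_sb,
    )


def lifetime_series(ensemble: Ensemble, contact_id: tuple,
                    criteria: ContactCriteria = ContactCriteria()
                    ) -> tuple[np.ndarray, float]:
    """Presence of one partner-level contact across frames, plus occupancy.

    ``contact_id`` is (kind, label_a, label_b), e.g.
    ``("saltbridge", "LYS12", "ASP11")``; partner order is irrelevant.
    """
    kind, la, lb = contact_id
    want = (kind,) + tuple(sorted((la, lb)))
    detector = {"hbond": detect_hbonds, "saltbridge": detect_salt_bridges}
    present = []
    for frame in ensemble.frames:
        if kind == "hydrophobic":
            _, _, recs = hydrophobic_contact_atoms(
                frame, set(MODULE_IDS), set(MODULE_IDS), criteria)
        else:
            recs = detector[kind](frame, criteria)
        present.append(any(r.pair_key == want for r in recs))
    present = np.array(present, dtype=bool)
    return present, float(present.mean())


def contacts_to_frame(records: list[ContactRecord]) -> pd.DataFrame:
    """Flat table of contact records (one row per record) for CSV export."""
    rows = [{
        "frame": r.frame, "kind": r.kind,
        "partner_a": r.a.label, "module_a": r.a.module, "atom_a": r.a.atom,
        "partner_b": r.b.label, "module_b": r.b.module, "atom_b": r.b.atom,
        "distance": round(r.distance, 3),
    } for r in records]
    return pd.DataFrame(rows, columns=["frame", "kind", "partner_a", "module_a",
                                       "atom_a", "partner_b", "module_b",
                                       "atom_b", "distance"])
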
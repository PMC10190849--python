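"""Synthetic conformations, ensembles and assay data.

Real relaxation trajectories for these conjugates are not publicly
deposited, so every pipeline input is emulated:

* :func:`build_backbone` — ideal-geometry backbones (NeRF chain extension
  from bond/angle tables shipped as data) in helix, hairpin or extended
  motifs, with side chains transplanted at a default rotamer and ligands
  placed from their templates;
* :func:`plant_contacts` — joint least-squares placement of specific
  hydrogen bonds, salt bridges or hydrophobic contacts, verified by
  re-detection (generator-detector closure);
* :func:`perturb_ensemble` — i.i.d. Gaussian coordinate noise emulating
  frame-to-frame fluctuation;
* :func:`generate_titration` — two-segment ThT dose-response with a
  breakpoint at the nominal CAC and multiplicative noise.

These are idealized fixtures for validating detectors and estimators, not
physically realistic dynamics; planted fixtures may locally distort
covalent geometry, which the detectors do not consume.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import optimize
from scipy.spatial.transform import Rotation

from . import _data
from .assay import TitrationCurve
from .chemistry import (BACKBONE_NAMES, residue_template, sidechain_anchor_atom,
                        topology_atoms)
from .conjugate import ConjugateTopology, parse_conjugate_spec
from .geometry import kabsch_superpose
from .interactions import (ContactCriteria, detect_hbonds, detect_salt_bridges,
                           hydrophobic_contact_atoms)
from .structure import Conformation, Ensemble

DEFAULT_DOSES = tuple(3.125 * 2 ** k for k in range(8))   # 3.125..400 uM, two-fold


class SyntheticError(ValueError):
    pass


class PlantError(SyntheticError):
    """An infeasible or leaky contact plant (never silently dropped)."""


def _backbone_params() -> dict:
    return yaml.safe_load(_data.read_text("backbone.yaml"))


# ---------------------------------------------------------------------------
# Ideal-geometry builder
# ---------------------------------------------------------------------------

@dataclass
class BackboneRecipe:
    topology: ConjugateTopology
    motif: str = "hairpin"                     # helix | hairpin | extended
    phi_psi_overrides: dict = field(default_factory=dict)  # index -> (phi, psi)
    turn_residues: tuple | None = None         # hairpin turn pair (defaults to centre)
    seed: int = 0

    @classmethod
    def from_sequence(cls, sequence: str, motif: str = "extended",
                      **kwargs) -> "BackboneRecipe":
        """Recipe for a bare peptide (single catch-all module)."""
        topo = parse_conjugate_spec(
            {"name": f"peptide-{sequence}",
             "segments": [{"module": "R1", "sequence": sequence}],
             "ligands": []})
        return cls(topology=topo, motif=motif, **kwargs)

    def intended_labels(self) -> dict[int, str]:
        """Secondary-structure labels the recipe aims for (termini coil)."""
        n = self.topology.n_residues
        per = self._phi_psi_table()
        out = {}
        for i in range(1, n + 1):
            if i in (1, n):
                out[i] = "C"
            else:
                phi, psi = per[i]
                if self.motif == "helix":
                    out[i] = "H"
                elif (-180 <= phi <= -45) and (45 <= psi <= 180):
                    out[i] = "E"
                else:
                    out[i] = "C"
        if self.phi_psi_overrides:
            from .geometry import HELIX_REGION, STRAND_REGION, _in_region
            for i, (phi, psi) in self.phi_psi_overrides.items():
                if i in (1, n):
                    continue
                if _in_region(phi, psi, HELIX_REGION):
                    out[i] = "H"
                elif _in_region(phi, psi, STRAND_REGION):
                    out[i] = "E"
                else:
                    out[i] = "C"
        return out

    def _phi_psi_table(self) -> dict[int, tuple]:
        params = _backbone_params()
        motifs = params["motifs"]
        n = self.topology.n_residues
        if self.motif == "helix":
            base = {i: (motifs["helix"]["phi"], motifs["helix"]["psi"])
                    for i in range(1, n + 1)}
        elif self.motif == "extended":
            base = {i: (motifs["extended"]["phi"], motifs["extended"]["psi"])
                    for i in range(1, n + 1)}
        elif self.motif == "hairpin":
            strand = motifs["hairpin"]["strand"]
            turns = motifs["hairpin"]["turn"]
            t1, t2 = self.turn_residues or (n // 2, n // 2 + 1)
            base = {i: (strand["phi"], strand["psi"]) for i in range(1, n + 1)}
            base[t1] = (turns[0]["phi"], turns[0]["psi"])
            base[t2] = (turns[1]["phi"], turns[1]["psi"])
        else:
            raise SyntheticError(f"unknown motif {self.motif!r}")
        base.update({int(k): tuple(v) for k, v in self.phi_psi_overrides.items()})
        return base


def _place_atom(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """NeRF internal-to-Cartesian placement of atom d bonded to c."""
    angle, dihedral = np.radians(angle), np.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(recipe: BackboneRecipe) -> Conformation:
    """Ideal-geometry conformation for a topology: NeRF backbone, default
    side-chain rotamers, ligands placed at their anchors.

    Fully deterministic for a given recipe (no RNG is consumed; the seed
    field tags derived ensembles)."""
    topo = recipe.topology
    params = _backbone_params()
    bl, ang = params["bonds"], params["angles"]
    omega = params["omega"]
    phi_psi = recipe._phi_psi_table()

    n = topo.n_residues
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (bl["N_CA"], 0.0, 0.0)
    th = np.radians(ang["N_CA_C"])
    C[0] = CA[0] + bl["CA_C"] * np.array([-np.cos(th), np.sin(th), 0.0])
    for i in range(1, n):
        psi_prev = phi_psi[i][1]           # psi of previous residue (1-based index i)
        N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1],
                           bl["C_N"], ang["CA_C_N"], psi_prev)
        CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i],
                            bl["N_CA"], ang["C_N_CA"], omega)
        phi = phi_psi[i + 1][0]
        C[i] = _place_atom(C[i - 1], N[i], CA[i],
                           bl["CA_C"], ang["N_CA_C"], phi)
    for i in range(n):
        psi = phi_psi[i + 1][1]
        O[i] = _place_atom(N[i], CA[i], C[i],
                           bl["C_O"], ang["CA_C_O"], psi - 180.0)

    atoms = topology_atoms(topo)
    coords = np.zeros((len(atoms), 3))
    pos_of = {}
    for k, atom in enumerate(atoms):
        if atom.ligand is None and atom.name in BACKBONE_NAMES:
            i = atom.residue_index - 1
            coords[k] = {"N": N[i], "CA": CA[i], "C": C[i], "O": O[i]}[atom.name]
            pos_of[(atom.residue_index, atom.name)] = coords[k]

    # side chains: superpose each residue template's (N, CA, C) frame
    for res in topo.residues:
        tpl = residue_template(res.code)
        side = [nm for nm in tpl.atom_names if nm not in BACKBONE_NAMES]
        if not side:
            continue
        i = res.index - 1
        frame_t = np.array([tpl.coords["N"], tpl.coords["CA"], tpl.coords["C"]])
        frame_b = np.array([N[i], CA[i], C[i]])
        sup = kabsch_superpose(frame_t, frame_b)
        for k, atom in enumerate(atoms):
            if atom.ligand is None and atom.residue_index == res.index \
                    and atom.name in side:
                coords[k] = sup.apply(tpl.coords[atom.name][None])[0]
                pos_of[(res.index, atom.name)] = coords[k]

    centroid = CA.mean(axis=0)
    for lig in topo.ligands:
        tplL = lig.template
        res = topo.residues[lig.anchor - 1]
        if lig.site == "side_chain":
            anchor_name = sidechain_anchor_atom(res.code)
        elif lig.site == "C_term":
            anchor_name = "C"
        else:
            anchor_name = "N"
        p = pos_of[(lig.anchor, anchor_name)]
        u = p - centroid
        nu = np.linalg.norm(u)
        u = u / nu if nu > 1e-9 else np.array([0.0, 0.0, 1.0])
        rot, _ = Rotation.align_vectors(u[None], np.array([[1.0, 0.0, 0.0]]))
        attach_xyz = np.array(dict(
            (a.name, a.xyz) for a in tplL.atoms)[tplL.attachment])
        origin = p + 1.8 * u
        for k, atom in enumerate(atoms):
            if atom.ligand == lig.label:
                local = np.array(dict(
                    (a.name, a.xyz) for a in tplL.atoms)[atom.name])
                coords[k] = origin + rot.apply(local - attach_xyz)

    return Conformation(topology=topo, atoms=atoms, coords=coords)


# ---------------------------------------------------------------------------
# Contact planting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedContact:
    kind: str                      # hbond | saltbridge | hydrophobic
    partner_a: int | str           # residue index or ligand label
    atom_a: str
    partner_b: int | str
    atom_b: str
    distance: float                # target, must satisfy the detector cutoff

    def label(self, topo: ConjugateTopology, which: str) -> str:
        p = self.partner_a if which == "a" else self.partner_b
        if isinstance(p, str):
            return p
        return topo.residues[p - 1].label


def _atom_index(conformation: Conformation, partner, atom_name: str) -> int:
    for i, a in enumerate(conformation.atoms):
        if isinstance(partner, str):
            if a.ligand == partner and a.name == atom_name:
                return i
        elif a.ligand is None and a.residue_index == partner and a.name == atom_name:
            return i
    raise PlantError(f"no atom {atom_name!r} on partner {partner!r}")


def _movable_unit(conformation: Conformation, partner, atom_name: str
                  ) -> tuple[tuple, np.ndarray, float]:
    """(unit key, atom indices, restraint weight) for the minimal rigid group
    moved to satisfy a plant: single ligand atom < side chain < whole residue,
    with restraint weights growing in that order.  Ligand atoms move
    individually — fixtures trade covalent realism for exact contact
    geometry."""
    atoms = conformation.atoms
    if isinstance(partner, str):
        i = _atom_index(conformation, partner, atom_name)
        return ("lig-atom", partner, atom_name), np.array([i]), 0.005
    if atom_name in BACKBONE_NAMES:
        idx = [k for k, a in enumerate(atoms)
               if a.ligand is None and a.residue_index == partner]
        return ("residue", partner), np.array(idx), 0.05
    idx = [k for k, a in enumerate(atoms)
           if a.ligand is None and a.residue_index == partner
           and a.name not in BACKBONE_NAMES]
    return ("sidechain", partner), np.array(idx), 0.02


def _resolve_units(conformation: Conformation, requests: list[tuple]
                   ) -> tuple[dict, dict]:
    """Merge overlapping movable units (side chain within whole residue,
    ligand charge group within whole ligand) so every atom belongs to at
    most one unit, and map each request to its resolved unit key."""
    raw: dict[tuple, tuple] = {}
    for partner, atom_name in requests:
        key, idx, w = _movable_unit(conformation, partner, atom_name)
        raw.setdefault(key, (idx, w, partner, atom_name))
    merged: dict[tuple, tuple] = {}
    alias: dict[tuple, tuple] = {}
    for key, (idx, w, partner, atom_name) in raw.items():
        target = key
        if key[0] == "sidechain" and ("residue", key[1]) in raw:
            target = ("residue", key[1])
        alias[key] = target
        if target == key:
            merged[key] = (idx, w)
    return merged, alias


def _contact_census(conformation: Conformation, plants, criteria):
    """Compare detected contacts against the plant list at the resolution
    the detectors count: hydrogen bonds per donor/acceptor atom pair, salt
    bridges per charge-group pair; restricted to the module pairs and kinds
    the plant list names.  Returns per-kind (wanted, got, leak records)."""
    topo = conformation.topology
    module_pairs = set()
    for p in plants:
        ma = topo.module_of(p.partner_a)
        mb = topo.module_of(p.partner_b)
        module_pairs.add(tuple(sorted((ma, mb))))
    serial_to_index = {a.serial: i for i, a in enumerate(conformation.atoms)}

    out = {}
    kinds = {p.kind for p in plants} & {"hbond", "saltbridge"}
    for kind in kinds:
        wanted = set()
        for p in (q for q in plants if q.kind == kind):
            ia = _atom_index(conformation, p.partner_a, p.atom_a)
            ib = _atom_index(conformation, p.partner_b, p.atom_b)
            if kind == "hbond":
                wanted.add(frozenset((ia, ib)))
            else:
                wanted.add(frozenset((conformation.atoms[ia].charge_group,
                                      conformation.atoms[ib].charge_group)))
        detector = detect_hbonds if kind == "hbond" else detect_salt_bridges
        got, leaks = set(), []
        for r in detector(conformation, criteria):
            if tuple(sorted((r.a.module, r.b.module))) not in module_pairs:
                continue
            ia = serial_to_index[r.a.serial]
            ib = serial_to_index[r.b.serial]
            if kind == "hbond":
                key = frozenset((ia, ib))
            else:
                key = frozenset((conformation.atoms[ia].charge_group,
                                 conformation.atoms[ib].charge_group))
            got.add(key)
            if key not in wanted:
                leaks.append((ia, ib, r))
        out[kind] = (wanted, got, leaks)
    return out


def _leak_repulsions(conformation: Conformation, plants, criteria
                     ) -> list[tuple]:
    """(i, j, min_distance) atom pairs to push apart: every detected contact
    not in the plant list, at the census resolution."""
    census = _contact_census(conformation, plants, criteria)
    repulsions = []
    for kind, (_, _, leaks) in census.items():
        if kind == "hbond":
            clearance = criteria.hbond_distance + 0.4
            repulsions.extend((ia, ib, clearance) for ia, ib, _ in leaks)
        else:
            clearance = criteria.saltbridge_distance + 0.4
            for ia, ib, _ in leaks:
                ga = conformation.atoms[ia].charge_group
                gb = conformation.atoms[ib].charge_group
                ga_idx = [k for k, a in enumerate(conformation.atoms)
                          if a.charge_group == ga]
                gb_idx = [k for k, a in enumerate(conformation.atoms)
                          if a.charge_group == gb]
                repulsions.extend((i, j, clearance)
                                  for i in ga_idx for j in gb_idx)
    return repulsions


def plant_contacts(conformation: Conformation,
                   plants: list[PlantedContact],
                   criteria: ContactCriteria = ContactCriteria(),
                   verify: bool = True, max_rounds: int = 8) -> Conformation:
    """Move minimal rigid units so every planted contact satisfies its
    detector criterion and no unplanted contact of a planted kind remains
    between the module pairs the plant list names.

    Joint least squares over per-unit rigid translations: attraction
    residuals hold each planted atom pair at its target distance, repulsion
    residuals push detected leaks beyond the cutoff, and weak position
    restraints keep every unit near its start.  Leaks are discovered by
    re-detection and the solve is repeated with accumulated repulsions
    (generator-detector closure); an infeasible plant list raises
    :class:`PlantError` rather than being silently dropped.
    """
    if not plants:
        return conformation
    topo = conformation.topology
    coords0 = conformation.coords
    cutoff = {"hbond": criteria.hbond_distance,
              "saltbridge": criteria.saltbridge_distance,
              "hydrophobic": criteria.hydrophobic_distance}

    requests = [(p.partner_a, p.atom_a) for p in plants] + \
               [(p.partner_b, p.atom_b) for p in plants]
    plant_atom_pairs = [
        (_atom_index(conformation, p.partner_a, p.atom_a),
         _atom_index(conformation, p.partner_b, p.atom_b),
         p.distance) for p in plants]

    repulsions: list[tuple] = []
    planted = conformation
    warm: dict[tuple, np.ndarray] = {}
    for _ in range(max_rounds):
        # movable units: from plants plus every atom involved in a repulsion
        atoms = conformation.atoms
        req = list(requests)
        for i, j, _ in repulsions:
            for k in (i, j):
                a = atoms[k]
                partner = a.ligand if a.ligand is not None else a.residue_index
                req.append((partner, a.name))
        units, alias = _resolve_units(conformation, req)
        atom_unit: dict[int, int] = {}
        keys = list(units)
        key_pos = {k: i for i, k in enumerate(keys)}
        for key, (idx, _) in units.items():
            for i in idx:
                atom_unit[int(i)] = key_pos[key]
        n_units = len(keys)
        # vectorised residual model: unit index -1 means immobile
        all_pairs = plant_atom_pairs + [(i, j, d) for i, j, d in repulsions]
        ia_arr = np.array([p[0] for p in all_pairs], dtype=int)
        ib_arr = np.array([p[1] for p in all_pairs], dtype=int)
        d_arr = np.array([p[2] for p in all_pairs])
        ua = np.array([atom_unit.get(int(i), -1) for i in ia_arr])
        ub = np.array([atom_unit.get(int(i), -1) for i in ib_arr])
        n_plants = len(plant_atom_pairs)
        weights = np.array([units[k][1] for k in keys])

        def residuals(x):
            t = np.vstack([x.reshape(-1, 3), np.zeros(3)])   # row -1 immobile
            diff = (coords0[ia_arr] + t[ua]) - (coords0[ib_arr] + t[ub])
            d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
            res = np.empty(len(all_pairs))
            res[:n_plants] = 10.0 * (d[:n_plants] - d_arr[:n_plants])
            res[n_plants:] = 10.0 * np.clip(d_arr[n_plants:] - d[n_plants:],
                                            0.0, None)
            restraint = (weights[:, None] * t[:n_units]).ravel()
            return np.concatenate([res, restraint])

        x_init = np.concatenate([warm.get(k, np.zeros(3)) for k in keys]) \
            if keys else np.zeros(0)
        sol = optimize.least_squares(residuals, x_init, method="trf",
                                     xtol=1e-12)
        t = sol.x.reshape(-1, 3)
        warm = {k: t[key_pos[k]].copy() for k in keys}
        new_coords = coords0.copy()
        for k in keys:
            new_coords[units[k][0]] += t[key_pos[k]]
        planted = Conformation(topology=topo, atoms=conformation.atoms,
                               coords=new_coords,
                               frame_index=conformation.frame_index)

        failures = []
        for p, (ia, ib, target) in zip(plants, plant_atom_pairs):
            d = float(np.linalg.norm(planted.coords[ia] - planted.coords[ib]))
            if abs(d - target) > 0.15 or d > cutoff[p.kind]:
                failures.append(
                    f"{p.kind} {p.partner_a}:{p.partner_b} at {d:.2f} A "
                    f"(target {target} A)")
        if failures:
            raise PlantError("infeasible plants: " + "; ".join(failures))

        new_leaks = _leak_repulsions(planted, plants, criteria)
        if not new_leaks:
            break
        before = len(repulsions)
        repulsions = sorted(set(repulsions) | set(new_leaks))
        if len(repulsions) == before:      # pragma: no cover
            break
    if verify:
        verify_plants(planted, plants, criteria)
    return planted


def verify_plants(conformation: Conformation, plants: list[PlantedContact],
                  criteria: ContactCriteria = ContactCriteria()) -> None:
    """Generator-detector closure: on the module pairs the plant list names,
    detected contacts equal planted ones — per donor/acceptor atom pair for
    hydrogen bonds, per charge-group pair for salt bridges."""
    census = _contact_census(conformation, plants, criteria)
    for kind, (wanted, got, leaks) in census.items():
        if got != wanted:
            extra = [f"{r.a.label}({r.a.atom}):{r.b.label}({r.b.atom})"
                     for _, _, r in leaks]
            missing = len(wanted - got)
            raise PlantError(
                f"{kind} closure failed: {missing} planted contact(s) "
                f"undetected, extra={extra}")


# ---------------------------------------------------------------------------
# Ensembles and titrations
# ---------------------------------------------------------------------------

def perturb_ensemble(conformation: Conformation, amplitude: float,
                     n_frames: int, seed: int = 0) -> Ensemble:
    """Gaussian-perturbed ensemble: frame 0 is the input; each later frame
    adds i.i.d. N(0, amplitude^2) displacement per atom per axis."""
    if amplitude < 0:
        raise SyntheticError("amplitude must be >= 0")
    if n_frames < 1:
        raise SyntheticError("need at least one frame")
    rng = np.random.default_rng(seed)
    stack = [conformation.coords.copy()]
    for _ in range(n_frames - 1):
        stack.append(conformation.coords
                     + rng.normal(0.0, amplitude, conformation.coords.shape))
    return Ensemble.from_coords(conformation.topology, np.stack(stack),
                                atoms=conformation.atoms)


def generate_titration(cac: float, pre_slope: float = 5.0,
                       post_slope: float = 120.0,
                       doses=DEFAULT_DOSES, noise_cv: float = 0.05,
                       seed: int = 0, baseline: float = 50.0,
                       molecule: str = "", replicate=0) -> TitrationCurve:
    """Two-segment ThT dose-response with a breakpoint at ``cac`` (uM).

    Mean fluorescence is continuous piecewise-linear in log2 dose with the
    given slopes (AU per two-fold dilution step); multiplicative Gaussian
    noise of coefficient-of-variation ``noise_cv`` is applied per dose.  A
    breakpoint above the highest dose yields a single pre-slope segment
    (indistinguishable from no aggregation over the tested range).
    """
    if post_slope <= pre_slope:
        raise SyntheticError("post_slope must exceed pre_slope for an "
                             "aggregating molecule")
    doses = np.asarray(sorted(doses), dtype=float)
    x = np.log2(doses)
    xb = np.log2(cac)
    mean = baseline + pre_slope * (x - x[0]) \
        + (post_slope - pre_slope) * np.maximum(0.0, x - xb)
    rng = np.random.default_rng(seed)
    noisy = mean * (1.0 + noise_cv * rng.standard_normal(len(doses))) \
        if noise_cv > 0 else mean
    return TitrationCurve(concentrations=doses,
                          fluorescence=np.clip(noisy, 0.0, None),
                          molecule=molecule, replicate=replicate)
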
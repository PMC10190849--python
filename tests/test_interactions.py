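"""Contact detectors against planted geometry and brute-force oracles."""
import numpy as np
import pytest

import modpep as mp
from conftest import random_two_module_conformation
from modpep.interactions import ContactCriteria

CRIT = ContactCriteria()


# -- independent all-pairs oracles (no KD-trees, no shortcuts) --------------

def oracle_hbond_pairs(conf, criteria=CRIT):
    anchors = {(l.label, l.anchor) for l in conf.topology.ligands}
    out = set()
    for i, a in enumerate(conf.atoms):
        if not a.donor:
            continue
        for j, b in enumerate(conf.atoms):
            if i == j or not b.acceptor or a.parent == b.parent:
                continue
            if a.ligand and (a.ligand, b.residue_index) in anchors:
                continue
            if b.ligand and (b.ligand, a.residue_index) in anchors:
                continue
            if (a.ligand is None and b.ligand is None and a.name == "N"
                    and b.name == "O"
                    and a.residue_index == b.residue_index + 1):
                continue
            if np.linalg.norm(conf.coords[i] - conf.coords[j]) \
                    <= criteria.hbond_distance:
                out.add((i, j))
    return out


def oracle_saltbridge_pairs(conf, criteria=CRIT):
    anchors = {(l.label, l.anchor) for l in conf.topology.ligands}
    groups = {}
    for i, a in enumerate(conf.atoms):
        if a.charge_group:
            groups.setdefault(a.charge_group, []).append(i)
    out = set()
    for gp, pi in groups.items():
        if conf.atoms[pi[0]].charge_sign != "cationic":
            continue
        for gn, ni in groups.items():
            if conf.atoms[ni[0]].charge_sign != "anionic":
                continue
            a, b = conf.atoms[pi[0]], conf.atoms[ni[0]]
            if a.parent == b.parent:
                continue
            if a.ligand and (a.ligand, b.residue_index) in anchors:
                continue
            if b.ligand and (b.ligand, a.residue_index) in anchors:
                continue
            dmin = min(np.linalg.norm(conf.coords[i] - conf.coords[j])
                       for i in pi for j in ni)
            if dmin <= criteria.saltbridge_distance:
                out.add((gp, gn))
    return out


def oracle_hydrophobic_atoms(conf, part_a, part_b, criteria=CRIT):
    topo = conf.topology
    engaged = set()
    for i, a in enumerate(conf.atoms):
        if not a.apolar or topo.module_of(a) not in part_a:
            continue
        for j, b in enumerate(conf.atoms):
            if j == i or not b.apolar or topo.module_of(b) not in part_b:
                continue
            if a.parent == b.parent:
                continue
            if (a.ligand is None and b.ligand is None
                    and abs(a.residue_index - b.residue_index) == 1):
                continue
            anchors = {(l.label, l.anchor) for l in topo.ligands}
            if a.ligand and (a.ligand, b.residue_index) in anchors:
                continue
            if b.ligand and (b.ligand, a.residue_index) in anchors:
                continue
            if np.linalg.norm(conf.coords[i] - conf.coords[j]) \
                    <= criteria.hydrophobic_distance:
                engaged.add(a.serial)
                engaged.add(b.serial)
    return engaged


def _detected_hbond_pairs(conf):
    serial_to_idx = {a.serial: i for i, a in enumerate(conf.atoms)}
    return {(serial_to_idx[r.a.serial], serial_to_idx[r.b.serial])
            for r in mp.detect_hbonds(conf)}


def test_planted_pair_inside_cutoff_detected(pbeta, pbeta_hairpin):
    recs = mp.detect_hbonds(pbeta_hairpin)
    # the ideal hairpin baseline keeps listed partners just outside range
    conf = mp.plant_contacts(
        pbeta_hairpin, [mp.PlantedContact("hbond", 16, "N", 3, "O", 2.9)])
    got = {r.pair_key for r in mp.detect_hbonds(conf)}
    assert ("hbond", "PHE16", "PRO3") in got


def test_pair_outside_cutoff_not_detected(pbeta_hairpin):
    with pytest.raises(mp.PlantError):
        # 3.8 A exceeds the 3.5 A criterion: the plant itself must refuse
        mp.plant_contacts(pbeta_hairpin,
                          [mp.PlantedContact("hbond", 16, "N", 3, "O", 3.8)])


def test_saltbridge_cutoff_behaviour(pbeta_hairpin):
    conf = mp.plant_contacts(
        pbeta_hairpin, [mp.PlantedContact("saltbridge", 12, "NZ", 11, "OD1", 3.7)])
    assert ("saltbridge", "ASP11", "LYS12") in \
        {r.pair_key for r in mp.detect_salt_bridges(conf)}
    far = mp.Conformation(topology=conf.topology, atoms=conf.atoms,
                          coords=conf.coords * 2.0)
    assert ("saltbridge", "ASP11", "LYS12") not in \
        {r.pair_key for r in mp.detect_salt_bridges(far)}


def test_detectors_equal_bruteforce_on_random_conformations():
    rng = np.random.default_rng(2024)
    for _ in range(12):
        conf = random_two_module_conformation(rng)
        assert _detected_hbond_pairs(conf) == oracle_hbond_pairs(conf)
        detected = {frozenset((r.a.label, r.b.label))
                    for r in mp.detect_salt_bridges(conf)}
        # oracle works on charge-group ids; map to parent labels
        label_of = {}
        for a in conf.atoms:
            if a.charge_group:
                label_of[a.charge_group] = a.parent_label
        want = {frozenset((label_of[gp], label_of[gn]))
                for gp, gn in oracle_saltbridge_pairs(conf)}
        assert detected == want
        n, atoms, _ = mp.hydrophobic_contact_atoms(conf, {"R1"}, {"R2"})
        want_atoms = oracle_hydrophobic_atoms(conf, {"R1"}, {"R2"})
        assert atoms == want_atoms and n == len(want_atoms)


def test_interdigitated_leucines_count_all_apolar_atoms():
    """Two Leu side chains fully within range: every apolar atom of both
    engages."""
    topo = mp.parse_conjugate_spec({
        "name": "LL",
        "segments": [{"module": "R1", "sequence": "GLG"},
                     {"module": "R2", "sequence": "GLG"}],
        "ligands": []})
    conf = mp.build_backbone(mp.BackboneRecipe(topology=topo, motif="extended"))
    coords = conf.coords.copy()
    # overlay residue 5's side chain onto residue 2's neighbourhood
    idx2 = conf.atom_indices(lambda a: a.residue_index == 2 and a.apolar)
    idx5 = conf.atom_indices(lambda a: a.residue_index == 5 and a.apolar)
    coords[idx5] = coords[idx2] + np.array([0.0, 0.0, 3.0])
    moved = mp.Conformation(topology=topo, atoms=conf.atoms, coords=coords)
    n, atoms, _ = mp.hydrophobic_contact_atoms(moved, {"R1"}, {"R2"})
    assert n == len(idx2) + len(idx5)


def test_polar_only_interface_counts_zero():
    topo = mp.parse_conjugate_spec({
        "name": "SS",
        "segments": [{"module": "R1", "sequence": "GSG"},
                     {"module": "R2", "sequence": "GSG"}],
        "ligands": []})
    conf = mp.build_backbone(mp.BackboneRecipe(topology=topo, motif="extended"))
    n, atoms, recs = mp.hydrophobic_contact_atoms(conf, {"R1"}, {"R2"})
    # serine has CB only (polar, bonded to OG); glycine has no side chain
    assert n == 0 and atoms == set() and recs == []


def test_distant_partitions_count_zero(pbeta, pbeta_hairpin):
    coords = pbeta_hairpin.coords.copy()
    r1 = pbeta_hairpin.module_indices("R1")
    coords[r1] += 100.0
    conf = mp.Conformation(topology=pbeta, atoms=pbeta_hairpin.atoms,
                           coords=coords)
    n, _, _ = mp.hydrophobic_contact_atoms(conf, {"R1"}, {"ASM"})
    assert n == 0


class TestLandscape:
    def test_mean_counts_are_framewise_means(self, pbeta, pbeta_planted,
                                             pbeta_hairpin):
        ens = mp.Ensemble(topology=pbeta,
                          frames=[pbeta_planted, pbeta_hairpin])
        land = mp.landscape(ens, pbeta)
        n0 = len(mp.detect_hbonds(pbeta_planted))
        n1 = len(mp.detect_hbonds(pbeta_hairpin))
        assert land.mean_total("hbond") == pytest.approx((n0 + n1) / 2)

    def test_single_frame_landscape_equals_frame_counts(self, pbeta,
                                                        pbeta_planted):
        ens = mp.Ensemble(topology=pbeta, frames=[pbeta_planted])
        land = mp.landscape(ens, pbeta)
        assert land.mean_total("hbond") == 4.0
        assert land.mean_total("saltbridge") == 2.0
        assert land.mean_total("saltbridge", inter=True) == 1.0   # LYS12:ASP11
        assert land.mean_total("saltbridge", inter=False) == 1.0  # LYS7:GLU9

    def test_inter_plus_intra_sums_to_total_every_frame(self, pbeta,
                                                        pbeta_ensemble):
        land = mp.landscape(pbeta_ensemble, pbeta)
        for kind in ("hbond", "saltbridge"):
            assert land.mean_total(kind) == pytest.approx(
                land.mean_total(kind, inter=True)
                + land.mean_total(kind, inter=False))
        for frame, recs in zip(pbeta_ensemble.frames, land.per_frame_hbonds):
            assert len(recs) == len(mp.detect_hbonds(frame))

    def test_occupancy_two_of_three_frames(self, pbeta, pbeta_planted,
                                           pbeta_hairpin):
        ens = mp.Ensemble(topology=pbeta,
                          frames=[pbeta_planted, pbeta_planted, pbeta_hairpin])
        land = mp.landscape(ens, pbeta)
        assert land.occupancy[("hbond", "PHE16", "PRO3")] == pytest.approx(2 / 3)


class TestLifetime:
    def test_always_present(self, pbeta, pbeta_planted):
        ens = mp.Ensemble(topology=pbeta, frames=[pbeta_planted] * 3)
        present, occ = mp.lifetime_series(ens, ("saltbridge", "LYS7", "GLU9"))
        assert present.all() and occ == 1.0

    def test_never_formed(self, pbeta, pbeta_hairpin):
        ens = mp.Ensemble(topology=pbeta, frames=[pbeta_hairpin] * 3)
        present, occ = mp.lifetime_series(ens, ("saltbridge", "LYS7", "GLU9"))
        assert not present.any() and occ == 0.0

    def test_alternating_frames_half_occupancy(self, pbeta, pbeta_planted,
                                               pbeta_hairpin):
        ens = mp.Ensemble(topology=pbeta, frames=[
            pbeta_planted, pbeta_hairpin, pbeta_planted, pbeta_hairpin])
        present, occ = mp.lifetime_series(ens, ("hbond", "ALA5", "VAL14"))
        assert occ == 0.5 and list(present) == [True, False, True, False]
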
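"""%SASA exposure statistic, dispersity classifier, cleavage delta."""
import numpy as np
import pytest

import modpep as mp
from conftest import random_two_module_conformation
from modpep.dispersity import DispersityError


def _single_frame(conf):
    return mp.Ensemble(topology=conf.topology, frames=[conf])


def test_asm_only_topology_is_fully_exposed():
    topo = mp.parse_conjugate_spec({
        "name": "bare", "segments": [{"module": "ASM", "sequence": "KLVFFAE"}],
        "ligands": []})
    conf = mp.build_backbone(mp.BackboneRecipe(topology=topo, motif="extended"))
    res = mp.percent_sasa(_single_frame(conf), topo)
    assert res.percent_sasa == pytest.approx(100.0)
    assert res.classification == "assembly_prone"


def test_enclosing_shell_buries_the_module(pbeta, pbeta_hairpin):
    """ASM inside a dense occluding shell drops below 5% exposure."""
    asm = pbeta_hairpin.module_indices("ASM")
    r1 = pbeta_hairpin.module_indices("R1")
    coords = pbeta_hairpin.coords.copy()
    centre = coords[asm].mean(axis=0)
    coords[asm] = centre + (coords[asm] - coords[asm].mean(axis=0)) * 0.25
    # uniform spherical shell of R1 atoms just outside the shrunken module
    coords[r1] = centre + 5.0 * mp.sphere_points(len(r1))
    conf = mp.Conformation(topology=pbeta, atoms=pbeta_hairpin.atoms,
                           coords=coords)
    res = mp.percent_sasa(_single_frame(conf), pbeta)
    assert res.percent_sasa < 5.0


def test_deleting_all_context_restores_full_exposure(pbeta, pbeta_hairpin):
    asm = pbeta_hairpin.module_indices("ASM")
    bare = pbeta_hairpin.subset(asm)
    topo_asm = mp.parse_conjugate_spec({
        "name": "asm", "segments": [{"module": "ASM", "sequence": "KLVFFAE"}],
        "ligands": []})
    conf = mp.Conformation(topology=topo_asm, atoms=mp.topology_atoms(topo_asm),
                           coords=bare.coords)
    res = mp.percent_sasa(_single_frame(conf), topo_asm)
    assert res.percent_sasa == pytest.approx(100.0)


def test_percent_sasa_rigid_motion_invariant(pbeta, pbeta_hairpin):
    from scipy.spatial.transform import Rotation
    base = mp.percent_sasa(_single_frame(pbeta_hairpin), pbeta).percent_sasa
    rot = Rotation.random(random_state=3)
    moved = mp.Conformation(
        topology=pbeta, atoms=pbeta_hairpin.atoms,
        coords=rot.apply(pbeta_hairpin.coords) + np.array([5.0, -7.0, 2.0]))
    after = mp.percent_sasa(_single_frame(moved), pbeta).percent_sasa
    assert after == pytest.approx(base, abs=0.5)


def test_empty_module_rejected(pbeta, pbeta_ensemble):
    with pytest.raises(DispersityError):
        mp.percent_sasa(pbeta_ensemble, pbeta, module_id="R4")


class TestClassifier:
    @pytest.mark.parametrize("value,label", [
        (88.6, "assembly_prone"),     # low-dispersity R2-modified conjugate
        (45.3, "dispersed"),          # R4-modified conjugate
        (75.0, "dispersed"),          # strict-inequality convention
        (75.01, "assembly_prone"),
    ])
    def test_threshold_rule(self, value, label):
        assert mp.classify_dispersity(value) == label

    def test_threshold_must_be_interior(self):
        with pytest.raises(DispersityError):
            mp.classify_dispersity(50.0, threshold=0.0)


class TestHydrolysisDelta:
    def test_delta_nonnegative_on_random_fixtures(self):
        rng = np.random.default_rng(77)
        pos = 0
        for _ in range(10):
            conf = random_two_module_conformation(rng, box_scale=1.6)
            # graft a cleavage rule: cut between the two modules
            topo = conf.topology
            r1_end = topo.span("R1").end
            motif = topo.sequence[max(0, r1_end - 4):r1_end]
            if topo.sequence.count(motif) != 1:
                continue      # ambiguous cut site in a random sequence
            rule = mp.CleavageRule(motif=motif)
            pre, post, delta = mp.hydrolysis_exposure_delta(
                _single_frame(conf), topo, rule=rule, module_id="R2")
            assert delta >= -1e-9
            pos += delta > 0
        assert pos > 0

    def test_distant_modules_give_exactly_zero_delta(self, pbeta,
                                                     pbeta_hairpin):
        coords = pbeta_hairpin.coords.copy()
        coords[pbeta_hairpin.module_indices("R1")] += 200.0
        conf = mp.Conformation(topology=pbeta, atoms=pbeta_hairpin.atoms,
                               coords=coords)
        pre, post, delta = mp.hydrolysis_exposure_delta(_single_frame(conf),
                                                        pbeta)
        assert delta == 0.0
        assert pre.percent_sasa == pytest.approx(100.0)

    def test_buried_interface_gives_larger_delta_than_open_one(
            self, pbeta, pbeta_hairpin):
        """Planting R1-ASM hydrophobic burial raises the cleavage delta
        relative to a conformation whose R1 barely touches ASM."""
        ens = _single_frame(pbeta_hairpin)
        _, _, delta_contact = mp.hydrolysis_exposure_delta(ens, pbeta)
        coords = pbeta_hairpin.coords.copy()
        coords[pbeta_hairpin.module_indices("R1")] += 30.0
        apart = mp.Conformation(topology=pbeta, atoms=pbeta_hairpin.atoms,
                                coords=coords)
        _, _, delta_apart = mp.hydrolysis_exposure_delta(_single_frame(apart),
                                                         pbeta)
        assert delta_contact > delta_apart
        assert delta_apart == pytest.approx(0.0, abs=1e-9)
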
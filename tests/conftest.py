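import numpy as np
import pytest

import modpep as mp


@pytest.fixture(scope="session")
def pbeta():
    return mp.load_design("Pbeta")


@pytest.fixture(scope="session")
def pbeta_hairpin(pbeta):
    return mp.build_backbone(mp.BackboneRecipe(
        topology=pbeta, motif="hairpin", turn_residues=(9, 10)))


@pytest.fixture(scope="session")
def pbeta_ensemble(pbeta_hairpin):
    return mp.perturb_ensemble(pbeta_hairpin, amplitude=0.25, n_frames=3, seed=11)


@pytest.fixture(scope="session")
def pbeta_planted():
    return mp.pbeta_contact_fixture()


@pytest.fixture(scope="session")
def r4c_planted():
    return mp.pbeta_r4c_contact_fixture()


def random_two_module_conformation(rng, n_residues=None, box_scale=2.2):
    """A conjugate conformation with random coordinates, for detector and
    exposure property tests: two modules (R1/R2) with random sequences,
    atom positions uniform in a density-matched box."""
    codes = list("ACDEFGHIKLMNPQRSTVWY")
    if n_residues is None:
        n_residues = int(rng.integers(6, 18))
    n1 = int(rng.integers(2, n_residues - 1))
    seq1 = "".join(rng.choice(codes, n1))
    seq2 = "".join(rng.choice(codes, n_residues - n1))
    topo = mp.parse_conjugate_spec({
        "name": f"rand-{seq1}-{seq2}",
        "segments": [{"module": "R1", "sequence": seq1},
                     {"module": "R2", "sequence": seq2}],
        "ligands": [],
    })
    conf = mp.build_backbone(mp.BackboneRecipe(topology=topo, motif="extended"))
    side = box_scale * conf.n_atoms ** (1.0 / 3.0) * 1.8
    coords = rng.uniform(0.0, side, size=conf.coords.shape)
    return mp.Conformation(topology=topo, atoms=conf.atoms, coords=coords)
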
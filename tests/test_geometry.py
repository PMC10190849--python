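"""Geometry kernels: Shrake-Rupley SASA, Kabsch RMSD, RGYR, secondary
structure."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import modpep as mp
from modpep.geometry import GeometryError


def two_sphere_accessible(r1, r2, d, probe=1.4):
    """Closed-form accessible area of sphere 1 occluded by sphere 2."""
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4 * np.pi * R1 * R1
    if R1 + d <= R2:
        return 0.0
    if R2 + d <= R1:
        return 4 * np.pi * R1 * R1
    cos_t = (d * d + R1 * R1 - R2 * R2) / (2 * d * R1)
    return 2 * np.pi * R1 * R1 * (1 + cos_t)


class TestSASA:
    def test_isolated_carbon_matches_sphere_area(self):
        area = mp.shrake_rupley(np.zeros((1, 3)), np.array([1.7]), 1.4, 960)[0]
        assert area == pytest.approx(4 * np.pi * 3.1 ** 2, rel=5e-3)

    def test_distant_atoms_unoccluded(self):
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        areas = mp.shrake_rupley(coords, np.array([1.7, 1.7]), 1.4, 960)
        assert areas == pytest.approx([4 * np.pi * 3.1 ** 2] * 2, rel=5e-3)

    def test_two_sphere_overlap_matches_analytic_cap(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            r1, r2 = rng.uniform(1.2, 2.0, size=2)
            d = rng.uniform(0.8, (r1 + r2 + 2.8) * 0.98)
            got = mp.shrake_rupley(np.array([[0.0, 0, 0], [d, 0, 0]]),
                                   np.array([r1, r2]), 1.4, 960)[0]
            want = two_sphere_accessible(r1, r2, d)
            assert abs(got - want) <= 0.01 * 4 * np.pi * (r1 + 1.4) ** 2

    def test_coincident_atoms_mutually_occlude(self):
        areas = mp.shrake_rupley(np.zeros((2, 3)), np.array([1.7, 1.7]), 1.4, 480)
        assert areas == pytest.approx([0.0, 0.0])

    def test_deleting_occluder_never_decreases_area(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = 12
            coords = rng.uniform(0, 8.0, size=(n, 3))
            radii = rng.uniform(1.4, 1.9, size=n)
            base = mp.shrake_rupley(coords, radii, 1.4, 240)
            drop = int(rng.integers(n))
            keep = [i for i in range(n) if i != drop]
            after = mp.shrake_rupley(coords[keep], radii[keep], 1.4, 240)
            assert np.all(after >= base[keep] - 1e-9)

    def test_total_area_rotation_translation_invariant(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 9.0, size=(15, 3))
        radii = rng.uniform(1.4, 1.9, size=15)
        base = mp.shrake_rupley(coords, radii, 1.4, 960).sum()
        rot = Rotation.random(random_state=5).as_matrix()
        moved = coords @ rot.T + np.array([3.0, -2.0, 11.0])
        after = mp.shrake_rupley(moved, radii, 1.4, 960).sum()
        # lattice orientation changes which points survive; tolerance covers it
        assert after == pytest.approx(base, rel=5e-3)


class TestKabsch:
    def test_identical_sets_zero_rmsd(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        assert mp.kabsch_superpose(pts, pts).rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_copy_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        rot = Rotation.random(random_state=2)
        moved = rot.apply(pts) + np.array([1.0, -4.0, 2.5])
        res = mp.kabsch_superpose(moved, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(res.rotation @ res.rotation.T, np.eye(3),
                                   atol=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_matches_bruteforce_rotation_search(self):
        """Optimality against dense sampled rotations on 4-point toy sets."""
        rng = np.random.default_rng(9)
        mobile = rng.normal(size=(4, 3))
        reference = rng.normal(size=(4, 3))
        res = mp.kabsch_superpose(mobile, reference)
        m0 = mobile - mobile.mean(axis=0)
        r0 = reference - reference.mean(axis=0)
        samples = Rotation.random(20000, random_state=12)
        rotated = np.einsum("nij,kj->nki", samples.as_matrix(), m0)
        rmsds = np.sqrt(((rotated - r0) ** 2).sum(axis=(1, 2)) / len(m0))
        assert res.rmsd <= rmsds.min() + 1e-9
        assert rmsds.min() - res.rmsd < 0.05

    def test_symmetry_of_rmsd(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        assert mp.kabsch_superpose(a, b).rmsd == pytest.approx(
            mp.kabsch_superpose(b, a).rmsd, abs=1e-6)

    def test_degenerate_selection_rejected(self):
        line = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        with pytest.raises(GeometryError):
            mp.kabsch_superpose(line, line + 1.0)


class TestRMSDSeries:
    def test_constant_ensemble_all_zero(self, pbeta_hairpin, pbeta):
        ens = mp.perturb_ensemble(pbeta_hairpin, 0.0, 4, seed=0)
        values, mean = mp.rmsd_series(ens)
        assert values == pytest.approx(np.zeros(4), abs=1e-9)
        assert mean == 0.0

    def test_single_frame_mean_is_that_frame(self, pbeta, pbeta_hairpin):
        ens = mp.Ensemble(topology=pbeta, frames=[pbeta_hairpin])
        values, mean = mp.rmsd_series(ens)
        assert mean == values[0] == pytest.approx(0.0, abs=1e-12)

    def test_planted_balanced_displacement_recovered(self, pbeta, pbeta_hairpin):
        """A displacement field with zero net translation and rotation moment
        leaves the optimal superposition at identity, so RMSD equals the
        planted per-atom displacement exactly."""
        delta = 0.8
        ca = pbeta_hairpin.atom_indices(lambda a: a.name == "CA")
        ref = pbeta_hairpin.coords[ca]
        # symmetric point set: pairs (p, -p) about the centroid
        centred = ref - ref.mean(axis=0)
        pts = np.vstack([centred, -centred])
        disp = np.zeros_like(pts)
        half = len(centred)
        disp[:half:2] = disp[1:half:2] = [delta, 0, 0]
        disp[half::2] = disp[half + 1::2] = [-delta, 0, 0]
        moved = pts + disp
        res = mp.kabsch_superpose(moved, pts)
        assert res.rmsd == pytest.approx(delta, rel=1e-6)

    def test_gaussian_ensemble_rmsd_tracks_amplitude(self, pbeta_hairpin):
        amp = 0.5
        ens = mp.perturb_ensemble(pbeta_hairpin, amp, 30, seed=8)
        _, mean = mp.rmsd_series(ens, selection="all")
        nonzero = mean * 30 / 29        # frame 0 contributes zero
        assert nonzero == pytest.approx(amp * np.sqrt(3), rel=0.1)


class TestRGYR:
    def test_two_points(self, pbeta_hairpin):
        conf = mp.Conformation(
            topology=pbeta_hairpin.topology,
            atoms=pbeta_hairpin.atoms[:2],
            coords=np.array([[0.0, 0, 0], [4.0, 0, 0]]))
        assert mp.radius_of_gyration(conf) == pytest.approx(2.0)

    def test_square_corners(self, pbeta_hairpin):
        s = 3.0
        conf = mp.Conformation(
            topology=pbeta_hairpin.topology,
            atoms=pbeta_hairpin.atoms[:4],
            coords=np.array([[0, 0, 0], [s, 0, 0], [s, s, 0], [0, s, 0.0]]))
        assert mp.radius_of_gyration(conf) == pytest.approx(s / np.sqrt(2))

    def test_hairpin_more_compact_than_extended(self, pbeta, pbeta_hairpin):
        ext = mp.build_backbone(mp.BackboneRecipe(topology=pbeta,
                                                  motif="extended"))
        assert mp.radius_of_gyration(pbeta_hairpin) < mp.radius_of_gyration(ext)

    def test_linear_scaling(self, pbeta_hairpin):
        base = mp.radius_of_gyration(pbeta_hairpin)
        scaled = mp.Conformation(topology=pbeta_hairpin.topology,
                                 atoms=pbeta_hairpin.atoms,
                                 coords=pbeta_hairpin.coords * 2.5)
        assert mp.radius_of_gyration(scaled) == pytest.approx(2.5 * base)


class TestSecondaryStructure:
    def test_ideal_helix_labelled_H(self):
        conf = mp.build_backbone(mp.BackboneRecipe.from_sequence(
            "A" * 10, motif="helix"))
        labels = mp.assign_secondary_structure(conf)
        assert labels[1] == labels[10] == "C"
        assert all(labels[i] == "H" for i in range(2, 10))

    def test_ideal_strand_labelled_E(self):
        conf = mp.build_backbone(mp.BackboneRecipe.from_sequence(
            "V" * 9, motif="extended"))
        labels = mp.assign_secondary_structure(conf)
        assert all(labels[i] == "E" for i in range(2, 9))

    def test_mixed_recipe_matches_intended_labels(self):
        recipe = mp.BackboneRecipe.from_sequence(
            "AKLVFFAEGS", motif="extended",
            phi_psi_overrides={4: (-60.0, -45.0), 5: (-60.0, -45.0),
                               6: (60.0, 60.0)})
        conf = mp.build_backbone(recipe)
        assert mp.assign_secondary_structure(conf) == recipe.intended_labels()
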
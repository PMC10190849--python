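"""Core geometric computations.

* Shrake-Rupley solvent-accessible surface area on a deterministic
  generalized-spiral point lattice (no RNG, bit-stable for a fixed point
  count).
* Optimal rigid superposition (Kabsch) and RMSD series over ensembles.
* Mass-unweighted radius of gyration.
* Ramachandran-region secondary-structure assignment (hydrogen-free;
  rectangular (phi, psi) regions rather than full DSSP).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structure import Conformation, Ensemble


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SASAOptions:
    probe_radius: float = 1.4          # Angstrom (water probe)
    n_points: int = 960                # sphere sample points per atom
    radii_table_id: str = "bondi64"

    def __post_init__(self):
        if self.probe_radius < 0:
            raise GeometryError("probe radius must be >= 0")
        if self.n_points < 2:
            raise GeometryError("need at least 2 sphere points")


def sphere_points(n: int) -> np.ndarray:
    """Deterministic generalized-spiral (golden angle) unit-sphere lattice."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley(coords: np.ndarray, radii: np.ndarray,
                  probe_radius: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2).

    Coincident atoms mutually occlude: a lattice point lying exactly on a
    neighbour's expanded sphere counts as buried, so two identical atoms at
    zero distance both report zero area.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise GeometryError("coords must be (n, 3)")
    if np.any(radii <= 0):
        raise GeometryError("radii must be positive")
    n = len(coords)
    expanded = radii + probe_radius
    unit = sphere_points(n_points)
    areas = np.zeros(n)
    if n == 0:
        return areas
    tree = cKDTree(coords)
    rmax = expanded.max()
    for i in range(n):
        ri = expanded[i]
        neigh = [j for j in tree.query_ball_point(coords[i], ri + rmax)
                 if j != i and np.linalg.norm(coords[j] - coords[i]) < ri + expanded[j]]
        pts = coords[i] + ri * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > expanded[j] ** 2 * (1.0 + 1e-12)
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * ri * ri * accessible.sum() / n_points
    return areas


def sasa(conformation: Conformation,
         options: SASAOptions = SASAOptions()) -> np.ndarray:
    """Shrake-Rupley per-atom SASA for a conformation (A^2)."""
    radii = np.array([a.radius for a in conformation.atoms])
    return shrake_rupley(conformation.coords, radii,
                         options.probe_radius, options.n_points)


# ---------------------------------------------------------------------------
# Superposition / RMSD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray               # (3, 3) proper rotation
    translation: np.ndarray            # (3,) applied after rotation
    rmsd: float                        # Angstrom

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray
                     ) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Proper rotation only (no reflection).  Requires >= 3 non-collinear
    points in each set.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("selections must be matching (n, 3) arrays")
    n = len(mobile)
    if n < 3:
        raise GeometryError("need at least 3 points for superposition")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    m0, r0 = mobile - mc, reference - rc
    if np.linalg.matrix_rank(m0, tol=1e-8) < 2 or np.linalg.matrix_rank(r0, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear or duplicate) selection")
    rot, rssd = Rotation.align_vectors(r0, m0)
    rmsd = float(rssd / np.sqrt(n))
    R = rot.as_matrix()
    translation = rc - mc @ R.T
    return SuperpositionResult(rotation=R, translation=translation, rmsd=rmsd)


def _selection_indices(conformation: Conformation, selection) -> np.ndarray:
    """Resolve a selection: None -> backbone CA atoms; 'all'; 'backbone';
    an iterable of atom indices; or a predicate over atoms."""
    if selection is None or (isinstance(selection, str) and selection == "CA"):
        idx = conformation.atom_indices(lambda a: a.name == "CA")
    elif isinstance(selection, str) and selection == "all":
        idx = np.arange(conformation.n_atoms)
    elif isinstance(selection, str) and selection == "backbone":
        idx = conformation.atom_indices(
            lambda a: a.ligand is None and a.name in ("N", "CA", "C", "O"))
    elif isinstance(selection, str):
        raise GeometryError(f"unknown selection {selection!r}")
    elif callable(selection):
        idx = conformation.atom_indices(selection)
    else:
        idx = np.asarray(list(selection), dtype=int)
    if len(idx) == 0:
        raise GeometryError("empty selection")
    return idx


def rmsd_series(ensemble: Ensemble, reference: Conformation | None = None,
                selection=None) -> tuple[np.ndarray, float]:
    """Per-frame RMSD to a reference after optimal superposition, plus mean.

    Default reference is the first frame; default selection is backbone CA.
    """
    if reference is None:
        reference = ensemble.frames[0]
    idx = _selection_indices(reference, selection)
    ref = reference.coords[idx]
    values = np.array([
        kabsch_superpose(frame.coords[idx], ref).rmsd
        for frame in ensemble.frames
    ])
    return values, float(values.mean())


def radius_of_gyration(conformation: Conformation, selection=None) -> float:
    """Mass-unweighted radius of gyration of a selection (default: all atoms)."""
    if selection is None:
        selection = "all"
    idx = _selection_indices(conformation, selection)
    xyz = conformation.coords[idx]
    centred = xyz - xyz.mean(axis=0)
    return float(np.sqrt(np.einsum("ij,ij->", centred, centred) / len(xyz)))


# ---------------------------------------------------------------------------
# Backbone dihedrals and secondary structure
# ---------------------------------------------------------------------------

def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees for four points."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def backbone_dihedrals(conformation: Conformation) -> dict[int, tuple]:
    """(phi, psi) per residue index; None where undefined (termini)."""
    topo = conformation.topology
    pos: dict[tuple[int, str], np.ndarray] = {}
    for a, xyz in zip(conformation.atoms, conformation.coords):
        if a.ligand is None and a.name in ("N", "CA", "C"):
            pos[(a.residue_index, a.name)] = xyz
    out = {}
    for res in topo.residues:
        i = res.index
        try:
            phi = None if i == 1 else dihedral(
                pos[(i - 1, "C")], pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")])
            psi = None if i == topo.n_residues else dihedral(
                pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")], pos[(i + 1, "N")])
        except KeyError as e:   # pragma: no cover
            raise GeometryError(f"missing backbone atom {e.args[0]}") from None
        out[i] = (phi, psi)
    return out


# Rectangular Ramachandran regions, degrees: (phi_min, phi_max, psi_min, psi_max)
HELIX_REGION = (-120.0, -30.0, -90.0, 0.0)
STRAND_REGION = (-180.0, -45.0, 45.0, 180.0)


def _in_region(phi, psi, region) -> bool:
    lo_f, hi_f, lo_p, hi_p = region
    return lo_f <= phi <= hi_f and lo_p <= psi <= hi_p


def assign_secondary_structure(conformation: Conformation) -> dict[int, str]:
    """Per-residue label H (helix), E (extended/strand) or C (coil).

    Termini, which lack phi or psi, are labelled C.
    """
    labels = {}
    for i, (phi, psi) in backbone_dihedrals(conformation).items():
        if phi is None or psi is None:
            labels[i] = "C"
        elif _in_region(phi, psi, HELIX_REGION):
            labels[i] = "H"
        elif _in_region(phi, psi, STRAND_REGION):
            labels[i] = "E"
        else:
            labels[i] = "C"
    return labels
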
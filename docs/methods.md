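# Methods

This note records the models, conventions and numerical choices behind
`modpep`, and what the synthetic-data validation does and does not show
about real conjugates.

## Conjugate model

A conjugate is one peptide chain partitioned into modules R1 (targeting +
tailoring, ending in the caspase-3/7 substrate DEVD), optional R2/R4
insertions, the conserved assembly motif ASM = KLVFFAE, and an optional
drug module R3 anchored at the motif's lysine side-chain amine. Ligands
(Cy-type sulfonated cyanine, FITC, pyrene) are modelled only at the
resolution the analysis consumes: elements, van-der-Waals radii, apolar
flags, hydrogen-bond donor/acceptor flags and formal charge groups — no
bond orders or protonation equilibria. Conjugation neutralises the anchor
group (a ligand on a lysine amine removes its positive charge and donor
capability; a C-terminal ligand removes the terminal carboxylate).

The built-in registry encodes the eight screened designs as
(MDEKAQK | AVPIAQK) + DEVD + KLVFFAE with the R2/R4 insertions (GC + Cy at
R2; CG + Cy, FITC or PDIFD at R4; pyrene on the motif lysine for the
drug-loaded variant). Full sequences of these designs are not publicly
deposited; the reconstruction is pinned by the per-residue labels of the
reported contact analysis (PRO3, GLU9, ASP11, LYS12, VAL14, PHE16, ALA17
all match AVPIAQKDEVD|KLVFFAE numbered from 1), and the mutated control is
assumed to share the DEVD tailoring segment, since every design is
described as cleavable. Registry entries are data files and can be
overridden by user records with the same schema.

Cleavage cuts C-terminal to the last residue of every motif occurrence
(canonical caspase P1 = Asp). Products re-index from 1, ligands travel
with their anchor residue, and cleavage is idempotent on its own products.

## Per-atom chemistry

Structures are heavy-atom only; all detectors work without hydrogens.
Radii are Bondi (1964), element-keyed, shipped as data. Flags:

* apolar — C or S with no covalent N/O neighbour;
* donor — N/O bearing ≥1 hydrogen in the parent amino acid (backbone amide
  N except proline; the free N terminus), with anionic carboxylates forced
  to acceptor-only in chain context;
* acceptor — every O, plus nitrogens with no attached hydrogen;
* charge groups — Lys/Arg side chains and the free N terminus cationic;
  Asp/Glu side chains, the free C terminus, and ligand
  sulfonate/carboxylate groups anionic.

Side-chain connectivity and hydrogen counts come from seeded RDKit ETKDG
embeddings of single amino acids, computed once per process. This replaces
a hand-curated rotamer/connectivity table: it is deterministic for a fixed
RDKit version and keeps flags consistent with an actual molecular graph.

## Geometry

**SASA** is Shrake–Rupley with a deterministic generalized-spiral (golden
angle) lattice, default 960 points per atom and a 1.4 Å probe; no RNG, so
results are bit-stable. A lattice point is buried if it lies on or inside
any neighbour's expanded sphere, which makes coincident atoms mutually
occluding (a documented degenerate-input convention) and makes per-atom
accessibility monotone under occluder deletion — the property the exposure
delta theorem rests on. At 960 points, overlaps shallower than ≈0.2 Å of
sphere separation can fall between lattice points; tests of strict
positivity use that margin.

**Superposition** minimises RMSD over proper rotations
(`scipy` `Rotation.align_vectors`; no reflections), with degenerate
(collinear/duplicate, or <3-point) selections rejected. The RMSD series
defaults to backbone Cα atoms against the first frame. **RGYR** is
mass-unweighted. **Secondary structure** uses rectangular Ramachandran
regions — helix φ ∈ (−120°, −30°), ψ ∈ (−90°, 0°); strand
φ ∈ (−180°, −45°), ψ ∈ (45°, 180°); else coil; termini coil — a
deliberately hydrogen-free rule, not DSSP.

## Interaction detection

Defaults (conventions, configurable; the underlying assays fix none of
them): hydrogen bond ≤ 3.5 Å donor–acceptor heavy-atom distance, one
record per donor-atom/acceptor-atom pair (an angle criterion would apply
only if hydrogens were present); salt bridge ≤ 4.0 Å closest approach
between opposite charge groups, one record per group pair; hydrophobic
≤ 5.0 Å apolar pairs, reported as the number of distinct participating
atoms rather than pairs. Excluded as trivial covalent neighbours:
intra-parent pairs, the amide N(i+1)···O(i) pair, sequence-adjacent apolar
pairs, and ligand-to-own-anchor-residue pairs. Landscapes average
per-frame counts per module pair; occupancy is frames-present / total
frames at partner-pair resolution.

## Exposure statistic and classifier

%SASA divides the motif's in-context surface by its isolated-module
surface at identical coordinates. The baseline choice matters — tabulated
per-residue maxima would shift the scale — so the baseline is stamped into
every report and the 75% threshold is documented as applying to the
isolated-module normalization. The ensemble statistic is the mean of
per-frame percentages (the percent of per-frame means is exported
alongside). Classification is strict: exactly 75.0 counts as dispersed.
Post-cleavage exposure is computed at frozen coordinates with the removed
modules deleted — a stated simplification (no product relaxation) that
guarantees delta ≥ 0 and isolates the purely steric effect of losing the
occluding modules.

## CAC regression

Model: continuous two-segment line in x = log₂(concentration/µM),
F(x) = b₀ + b₁x + b₂·max(0, x − x_b), fitted by least squares with x_b on
a 200-point grid spanning the interior doses and polished by bounded
scalar minimization (noiseless curves recover the breakpoint to numerical
precision). A fit is a valid aggregation call only if b₂ > 0 and the
two-segment model beats a single line at α = 0.01 (F test, 2 numerator
df); otherwise the estimate is censored as "≥ max tested", matching how
no-signal designs are reported. The onset concentration (first tested
dose at or above the breakpoint) is reported alongside; the breakpoint is
primary. The default dose design is 8 two-fold dilutions, 3.125–400 µM.

## Synthetic data

The generator emulates the study's inputs, not its physics:

* **Backbones** by NeRF chain extension from ideal bond/angle tables
  (Engh–Huber consensus values, shipped as data) at motif (φ, ψ) values —
  helix (−60°, −45°), strand (−135°, 135°), and a two-residue hairpin turn
  (−9°, −136°) / (−7°, −77°) chosen once so the two strands run
  antiparallel with cross-strand N···O spacings of ≈4.2–6.5 Å: outside
  every contact cutoff, but within reach of the planting optimizer. Side
  chains are transplanted from the seeded RDKit templates at a default
  rotamer; ligands are placed 1.8 Å off their anchor, pointing away from
  the backbone centroid.
* **Contact planting** solves a joint least-squares problem over rigid
  translations of minimal movable units (single ligand atoms < side
  chains < whole residues, with position restraints growing in that
  order): attraction residuals hold planted atom pairs at their targets,
  repulsion residuals push detected unplanted contacts beyond cutoff +
  0.4 Å, and the solve iterates against re-detection until closure —
  detected contacts equal planted ones at the detectors' own counting
  resolution (atom pairs for hydrogen bonds, charge-group pairs for salt
  bridges) on the module pairs the plant list names. Infeasible plant
  lists raise, never drop. Planting deliberately trades covalent realism
  (bonds may stretch; ligand atoms move individually) for exact contact
  geometry: planted fixtures validate detector bookkeeping and counting
  conventions, not energetics.
* **Ensembles** add i.i.d. Gaussian per-atom displacement per frame
  (frame 0 is the input), so the expected all-atom RMSD to frame 0 is
  amplitude·√3 — a closed form the tests check.
* **Titrations** draw multiplicative Gaussian noise around the same
  two-segment model the estimator fits, with defaults (baseline 50 AU,
  slopes 5 and 120 AU per dilution step, 5% noise) chosen to resemble a
  plate-reader ThT series with a clear post-CAC rise.

The reference contact fixtures plant the canonical interaction patterns of
the Pbeta design (four hydrogen bonds PHE16:PRO3, VAL14:ALA5, LYS7:LYS12,
ALA5:VAL14; two salt bridges LYS12:ASP11, LYS7:GLU9) and of Pbeta_R4C (six
inter-module hydrogen bonds, three inter-module salt bridges including the
N-terminal ALA1:Cy bridge, one intra-module salt bridge), with
bridges-only planted at 3.7 Å (between the 3.5 Å hydrogen-bond and 4.0 Å
salt-bridge cutoffs) and the LYS12:Cy / ALA1:Cy pairs at 3.2 Å so they
register as both kinds, as reported.

**What passing tests show** — that the estimators recover exactly what was
planted, at the stated noise, and that the geometric kernels match closed
forms and brute-force enumeration. **What they do not show** — that
screen-computed %SASA values or interaction means predict measured
exposure percentages or trajectory-averaged counts for real conjugates:
synthetic ensembles are Gaussian clouds around one ideal conformation, not
Boltzmann ensembles, and printed study values that depend on unavailable
trajectories (mean RMSDs, exposure percentages, interaction averages) are
correspondingly out of scope for quantitative reproduction.

## Problem sizes and determinism

Default screens use 5-frame ensembles at 0.25 Å amplitude over the
8-design registry, 960 lattice points per atom — sizes chosen so a full
screen completes in seconds while keeping lattice error well under the
percentage-point scale of the statistic. Every stochastic step derives
from one seed (per-design child seeds via `SeedSequence`), and summary
CSVs are formatted to fixed precision, so identical configurations produce
byte-identical outputs.

## Known limitations

* Side-chain rotamers are single default conformers; no packing or clash
  relaxation is attempted anywhere.
* The hydrogen-bond criterion is distance-only on heavy atoms; geometries
  with poor N–H···A alignment are still counted.
* The %SASA threshold was established under one normalization; applying
  it to another baseline is not meaningful, and reports say so.
* Planted fixtures can contain locally distorted covalent geometry and
  ligand groups displaced from their cores; they are labelled synthetic
  and must not be read as physical conformations.
* CAC censoring depends on the α of the slope-increase test; very shallow
  post-breakpoint slopes near the top dose are censored rather than
  extrapolated.
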
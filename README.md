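# modpep

Conformational analysis of modular, enzymatically activated self-assembling
peptide–drug conjugates.

## The problem

Peptide–drug conjugates built around the amyloid-derived assembly motif
**KLVFFAE** are designed to circulate as dispersed monomers and to
self-assemble into nanofibers only after caspase-3/7 cleaves the **DEVD**
substrate in their targeting/tailoring segment. Whether a given modular
design (targeting segment R1, optional insertions R2/R4, drug site R3 on
the motif's lysine, dye labels such as sulfonated cyanine, FITC or pyrene)
stays soluble before activation depends on how well the other modules bury
the assembly motif. `modpep` provides the desk-scale analysis used to
screen such designs:

* **%SASA** — solvent exposure of the assembly motif, by Shrake–Rupley
  surface areas on a deterministic spiral lattice:

  `%SASA = 100 · SASA(ASM | whole conjugate) / SASA(ASM | isolated, same coordinates)`

  averaged over ensemble frames, with a 75% threshold separating
  assembly-prone (>75%) from dispersed designs.
* **Interaction landscapes** — hydrogen bonds (donor–acceptor heavy atoms
  ≤ 3.5 Å), salt bridges (opposite formal charge groups ≤ 4.0 Å closest
  approach) and hydrophobic contacts (apolar atom pairs ≤ 5.0 Å, counted
  as distinct participating atoms), aggregated per module pair with
  per-contact occupancies and lifetime series.
* **Cleavage-triggered exposure** — %SASA recomputed after deleting the
  cleaved-away modules at frozen coordinates; the exposure delta is
  non-negative by the occluder-removal theorem.
* **CAC estimation** — critical aggregation concentration from Thioflavin-T
  dose–response tables by continuous two-segment least squares on log₂
  concentration, with an F-test slope-increase criterion and "≥ max tested"
  censoring for designs with no aggregation signal.
* **Backbone metrics** — Kabsch RMSD series, radius of gyration, and a
  Ramachandran-region secondary-structure assignment (H/E/C).

Because the underlying relaxation trajectories and raw titration tables of
such designs are generally not deposited, the package ships a first-class
synthetic-data module: ideal-geometry backbones (helix / β-hairpin /
extended), planted contacts verified by re-detection, Gaussian-perturbed
ensembles, and two-segment titration curves — so every estimator can be
validated against inputs with known ground truth.

## Worked example

```python
import modpep as mp

topo = mp.load_design("Pbeta")            # AVPIAQKDEVD|KLVFFAE
conf = mp.build_backbone(mp.BackboneRecipe(topology=topo, motif="hairpin",
                                           turn_residues=(9, 10)))
ens = mp.perturb_ensemble(conf, amplitude=0.25, n_frames=5, seed=1)
pre, post, delta = mp.hydrolysis_exposure_delta(ens, topo)
print(f"precursor %SASA  : {pre.percent_sasa:6.2f}  -> {pre.classification}")
print(f"post-cleavage    : {post.percent_sasa:6.2f}  -> {post.classification}")
print(f"exposure delta   : {delta:+6.2f} percentage points")
```

prints

```
precursor %SASA  :  56.18  -> dispersed
post-cleavage    : 100.00  -> assembly_prone
exposure delta   : +43.82 percentage points
```

— on this synthetic hairpin ensemble, the R1 segment buries about 44% of
the assembly motif's surface, all of which is re-exposed once the DEVD cut
removes R1 (the product here is the bare motif, hence exactly 100%).

Fitting synthetic ThT titrations (8 two-fold dilutions, 5% noise):

```
   molecule cac_display  onset_uM  pre_slope  post_slope  p_value
    hairpin  26.0011 uM      50.0     4.4703    122.3835 0.000035
R2-labelled      200 uM     200.0     4.3276    107.9427 0.000089
R4-labelled   >= 400 uM       NaN    -2.2496     6.2818  0.496621
```

The breakpoints planted at 25 and 200 µM are recovered; the design whose
breakpoint lies above the tested range is censored.

The `examples/` directory contains one short narrative script per
capability; `modpep --help` exposes the same workflow as a CLI
(`screen`, `cac`, `cleave`, `landscape`, `synth`).

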
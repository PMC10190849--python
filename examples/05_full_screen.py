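"""End-to-end design screen.

Screens a subset of the built-in registry: synthetic ensemble -> backbone
stability (mean RMSD), assembly-motif compactness (RGYR), interaction
totals, %SASA classification and cleavage-triggered exposure, one row per
design.  Equivalent to `modpep screen --design Pbeta ...` on the command
line; with no --design flags the CLI screens all eight built-ins.
"""
from modpep.pipeline import RunConfig, run_cac_table, run_design_screen

cfg = RunConfig(designs=["Pbeta", "Pbeta_R2C", "Pbeta_R4C"],
                seed=1, n_frames=3, outdir="scratch/example_screen")
summary = run_design_screen(cfg)
print(summary.to_string(index=False))
print()
print(run_cac_table(cfg)[["molecule", "cac_display"]].to_string(index=False))
# percent_sasa ranks how much of each design's assembly motif stays
# solvent-exposed; exposure_delta shows how much cleavage un-buries it.
# Screen values are computed on idealized synthetic ensembles and rank
# designs; they are not predictions of measured exposure percentages.
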
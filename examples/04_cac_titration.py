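"""Critical aggregation concentration from ThT titrations.

Generates synthetic dose-response curves (8 two-fold dilutions, 3.125-400
uM, 5% multiplicative noise) for three regimes — an aggregating design with
a 25 uM breakpoint, one at 200 uM, and a soluble design whose breakpoint
lies above the tested range — and fits each by two-segment breakpoint
regression on log dose.  Soluble designs are censored as ">= 400 uM".
"""
import modpep as mp

curves = [
    mp.generate_titration(cac=25.0, noise_cv=0.05, seed=11, molecule="hairpin"),
    mp.generate_titration(cac=200.0, noise_cv=0.05, seed=12, molecule="R2-labelled"),
    mp.generate_titration(cac=800.0, noise_cv=0.05, seed=13, molecule="R4-labelled"),
]
table = mp.batch_cac(curves)
print(table[["molecule", "cac_display", "onset_uM", "pre_slope",
             "post_slope", "p_value"]].to_string(index=False))
# cac_display: fitted breakpoint, or the censoring bound when the
# slope-increase criterion finds no aggregation signal.  onset_uM is the
# first tested dose at or above the breakpoint (the value a plate reader
# experiment would quote).
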
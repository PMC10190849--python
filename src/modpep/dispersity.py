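"""The %SASA design statistic and the dispersity classifier.

%SASA measures how much of the assembly motif's surface remains
solvent-exposed in the context of the whole conjugate:

    %SASA = 100 * SASA(ASM atoms | full molecule)
                / SASA(ASM atoms | all non-ASM atoms deleted, same coords)

averaged over ensemble frames (mean of per-frame percentages; the percent
of per-frame means is also exported).  The denominator is the
isolated-module baseline at identical coordinates, so 0 <= %SASA <= 100 is
guaranteed by occlusion monotonicity.  An alternative baseline (tabulated
per-residue maxima) could be substituted; the baseline used is stamped into
every result.

A conjugate whose %SASA exceeds the threshold (default 75%) is classified
assembly_prone; at or below it, dispersed.  Cleavage-triggered exposure is
quantified by recomputing %SASA on identical coordinates with the
cleaved-away modules deleted (no relaxation of the product), so the
exposure delta is non-negative by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conjugate import CleavageRule, ConjugateTopology, cleave
from .geometry import SASAOptions, sasa
from .structure import Ensemble

DEFAULT_THRESHOLD = 75.0


class DispersityError(ValueError):
    pass


@dataclass
class ExposureResult:
    molecule: str
    module_id: str
    numerator_sasa: float              # ensemble-mean ASM SASA in context, A^2
    denominator_sasa: float            # ensemble-mean isolated-ASM SASA, A^2
    percent_sasa: float                # mean of per-frame percentages
    percent_of_means: float            # alternative statistic, exported alongside
    per_frame_percent: np.ndarray = field(repr=False, default=None)
    threshold: float = DEFAULT_THRESHOLD
    classification: str = ""
    baseline: str = "isolated_module"
    options: SASAOptions = field(default_factory=SASAOptions)

    def to_report(self) -> dict:
        return {
            "molecule": self.molecule,
            "module": self.module_id,
            "percent_sasa": round(self.percent_sasa, 2),
            "percent_of_means": round(self.percent_of_means, 2),
            "numerator_sasa_A2": round(self.numerator_sasa, 2),
            "denominator_sasa_A2": round(self.denominator_sasa, 2),
            "classification": self.classification,
            "threshold_percent": self.threshold,
            "baseline": self.baseline,
            "options": {
                "probe_radius_A": self.options.probe_radius,
                "sphere_points": self.options.n_points,
                "radii_table": self.options.radii_table_id,
            },
            "note": ("%SASA normalization is baseline-dependent; the "
                     "threshold applies to the isolated-module baseline."),
        }


def percent_sasa(ensemble: Ensemble, topology: ConjugateTopology | None = None,
                 module_id: str = "ASM",
                 options: SASAOptions = SASAOptions(),
                 threshold: float = DEFAULT_THRESHOLD) -> ExposureResult:
    """Ensemble-averaged %SASA of a module, with dispersity classification."""
    if topology is None:
        topology = ensemble.topology
    span = topology.span(module_id)
    if span is None:
        raise DispersityError(f"{topology.name}: no module {module_id!r}")
    idx = ensemble.frames[0].module_indices(module_id)
    if len(idx) == 0:
        raise DispersityError(f"{topology.name}: module {module_id} is empty")

    percents, nums, dens = [], [], []
    for frame in ensemble.frames:
        full = sasa(frame, options)
        isolated = sasa(frame.subset(idx), options)
        num, den = float(full[idx].sum()), float(isolated.sum())
        if den <= 0:
            raise DispersityError("isolated-module SASA vanished")
        percents.append(100.0 * num / den)
        nums.append(num)
        dens.append(den)
    percents = np.array(percents)
    mean_num, mean_den = float(np.mean(nums)), float(np.mean(dens))
    result = ExposureResult(
        molecule=topology.name, module_id=module_id,
        numerator_sasa=mean_num, denominator_sasa=mean_den,
        percent_sasa=float(percents.mean()),
        percent_of_means=100.0 * mean_num / mean_den,
        per_frame_percent=percents,
        threshold=threshold, options=options)
    result.classification = classify_dispersity(result, threshold)
    return result


def classify_dispersity(exposure, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Apply the exposure threshold: strictly above -> assembly_prone.

    Accepts an :class:`ExposureResult` or a bare percentage.  Exactly at the
    threshold counts as dispersed (strict-inequality convention).
    """
    if not 0 < threshold < 100:
        raise DispersityError("threshold must be inside (0, 100)")
    value = exposure.percent_sasa if isinstance(exposure, ExposureResult) else float(exposure)
    return "assembly_prone" if value > threshold else "dispersed"


def hydrolysis_exposure_delta(ensemble: Ensemble,
                              topology: ConjugateTopology | None = None,
                              rule: CleavageRule | None = None,
                              module_id: str = "ASM",
                              options: SASAOptions = SASAOptions(),
                              threshold: float = DEFAULT_THRESHOLD
                              ) -> tuple[ExposureResult, ExposureResult, float]:
    """Exposure change of the assembly module upon cleavage.

    The product's %SASA is computed on the precursor's coordinates with the
    cleaved-away modules' atoms deleted (coordinates frozen, no relaxation).
    Returns (precursor result, product result, delta in percentage points);
    delta >= 0 always, and delta == 0 exactly when no removed atom occludes
    the module.
    """
    if topology is None:
        topology = ensemble.topology
    pre = percent_sasa(ensemble, topology, module_id, options, threshold)

    products = cleave(topology, rule)
    keeper = None
    for p in products:
        if p.span(module_id) is not None and p.span(module_id).start is not None:
            keeper = p
            break
    if keeper is None:
        raise DispersityError(
            f"{topology.name}: no cleavage product retains module {module_id}")

    # map kept residues/ligands back to precursor atom indices
    lo = topology.sequence.find(keeper.sequence)
    kept_residues = set(range(lo + 1, lo + keeper.n_residues + 1))
    kept_ligands = {l.label for l in keeper.ligands}
    frame0 = ensemble.frames[0]
    keep_idx = frame0.atom_indices(
        lambda a: (a.ligand in kept_ligands) if a.ligand is not None
        else a.residue_index in kept_residues)

    idx_full = frame0.module_indices(module_id)
    keep_set = set(keep_idx.tolist())
    # position of module atoms inside the kept subset
    sub_positions = {g: k for k, g in enumerate(keep_idx)}
    idx_sub = np.array([sub_positions[i] for i in idx_full if i in keep_set])

    percents, nums, dens = [], [], []
    for frame in ensemble.frames:
        sub = frame.subset(keep_idx)
        full = sasa(sub, options)
        isolated = sasa(sub.subset(idx_sub), options)
        num, den = float(full[idx_sub].sum()), float(isolated.sum())
        percents.append(100.0 * num / den)
        nums.append(num)
        dens.append(den)
    percents = np.array(percents)
    post = ExposureResult(
        molecule=keeper.name, module_id=module_id,
        numerator_sasa=float(np.mean(nums)),
        denominator_sasa=float(np.mean(dens)),
        percent_sasa=float(percents.mean()),
        percent_of_means=100.0 * float(np.mean(nums)) / float(np.mean(dens)),
        per_frame_percent=percents, threshold=threshold, options=options)
    post.classification = classify_dispersity(post, threshold)
    return pre, post, post.percent_sasa - pre.percent_sasa
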
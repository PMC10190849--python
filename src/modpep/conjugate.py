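"""Modular peptide-drug conjugate topologies.

A conjugate is a single peptide chain partitioned into named functional
modules — R1 (targeting + tailoring), R2, ASM (the conserved assembly motif
KLVFFAE), R3 (drug) and R4 — plus ligands (dyes, drug) attached to anchor
residues.  The caspase-3/7 cleavage operation cuts C-terminal to the last
residue of the DEVD recognition motif and converts the soluble precursor
into the assembling residue fragment.

Topologies are declarative: they carry sequence, module partition, ligand
attachments and the cleavage rule, but no coordinates.  Conformations bind
coordinates to a topology (see :mod:`modpep.structure`).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from . import _data

MODULE_IDS = ("R1", "R2", "ASM", "R3", "R4")
ASM_SEQUENCE = "KLVFFAE"
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
ONE_LETTER = {v: k for k, v in THREE_LETTER.items()}

ANCHOR_SITES = ("side_chain", "C_term", "N_term")


class TopologyError(ValueError):
    """Raised for invalid conjugate design records."""


@dataclass(frozen=True)
class Residue:
    index: int              # 1-based, contiguous within the chain
    code: str               # one-letter amino-acid code
    is_N_terminal: bool = False
    is_C_terminal: bool = False

    @property
    def label(self) -> str:
        """Residue label in the convention of contact reports, e.g. LYS12."""
        return f"{THREE_LETTER[self.code]}{self.index}"


@dataclass(frozen=True)
class LigandAtom:
    name: str
    element: str
    xyz: tuple[float, float, float]
    apolar: bool = False
    donor: bool = False
    acceptor: bool = False
    charge_group: str | None = None
    charge_sign: str | None = None    # cationic | anionic | None


@dataclass(frozen=True)
class LigandTemplate:
    name: str                          # registry identifier, e.g. "Cy"
    resname: str                       # 3-letter HETATM residue name
    atoms: tuple[LigandAtom, ...]
    bonds: tuple[tuple[str, str], ...]
    attachment: str                    # atom name bonded to the anchor
    description: str = ""

    def __post_init__(self):
        if not self.atoms:
            raise TopologyError(f"ligand template {self.name!r} has no atoms")
        names = [a.name for a in self.atoms]
        if len(set(names)) != len(names):
            raise TopologyError(f"duplicate atom names in ligand {self.name!r}")
        if self.attachment not in names:
            raise TopologyError(
                f"ligand {self.name!r}: attachment atom {self.attachment!r} missing")
        groups = {a.charge_group for a in self.atoms if a.charge_group}
        for g in groups:
            if not any(a.charge_group == g for a in self.atoms):
                raise TopologyError(f"empty charge group {g!r} in {self.name!r}")


@dataclass(frozen=True)
class LigandAttachment:
    label: str                         # instance label, unique per topology
    template: LigandTemplate
    anchor: int                        # anchor residue index
    site: str                          # side_chain | C_term | N_term
    module_id: str


@dataclass(frozen=True)
class ModuleSpan:
    """Closed 1-based residue range and/or ligand labels owned by a module."""
    module_id: str
    start: int | None = None
    end: int | None = None
    ligands: tuple[str, ...] = ()

    @property
    def residue_indices(self) -> range:
        if self.start is None:
            return range(0)
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class CleavageRule:
    motif: str = "DEVD"                # cut C-terminal to the motif's last residue

    def __post_init__(self):
        if not self.motif:
            raise TopologyError("cleavage motif must be non-empty")


@dataclass(frozen=True)
class ConjugateTopology:
    name: str
    residues: tuple[Residue, ...]
    spans: tuple[ModuleSpan, ...]
    ligands: tuple[LigandAttachment, ...]
    cleavage_rule: CleavageRule | None = None
    _residue_module: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        rmap: dict[int, str] = {}
        for span in self.spans:
            for i in span.residue_indices:
                if i in rmap:
                    raise TopologyError(
                        f"{self.name}: residue {i} covered by modules "
                        f"{rmap[i]} and {span.module_id}")
                rmap[i] = span.module_id
        indices = [r.index for r in self.residues]
        if indices != list(range(1, len(indices) + 1)):
            raise TopologyError(f"{self.name}: residue numbering not contiguous from 1")
        missing = [i for i in indices if i not in rmap]
        if missing:
            raise TopologyError(f"{self.name}: residues {missing} not covered by any module")
        extra = [i for i in rmap if i not in set(indices)]
        if extra:
            raise TopologyError(f"{self.name}: module spans reference absent residues {extra}")
        lig_labels = [l.label for l in self.ligands]
        if len(set(lig_labels)) != len(lig_labels):
            raise TopologyError(f"{self.name}: duplicate ligand labels")
        span_ligs = [lab for s in self.spans for lab in s.ligands]
        if sorted(span_ligs) != sorted(lig_labels):
            raise TopologyError(f"{self.name}: ligands and module spans disagree")
        for lig in self.ligands:
            if lig.anchor not in rmap:
                raise TopologyError(
                    f"{self.name}: ligand {lig.label} anchored at absent residue {lig.anchor}")
            if lig.site not in ANCHOR_SITES:
                raise TopologyError(f"{self.name}: bad anchor site {lig.site!r}")
            if lig.module_id == "R3":
                code = self.residues[lig.anchor - 1].code
                if code != "K" or lig.site != "side_chain":
                    raise TopologyError(
                        f"{self.name}: drug (R3) ligand {lig.label} must anchor at a "
                        f"lysine side-chain amine, got {code}/{lig.site}")
        object.__setattr__(self, "_residue_module", rmap)

    # -- queries -----------------------------------------------------------
    @property
    def sequence(self) -> str:
        return "".join(r.code for r in self.residues)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def span(self, module_id: str) -> ModuleSpan | None:
        for s in self.spans:
            if s.module_id == module_id:
                return s
        return None

    def ligand(self, label: str) -> LigandAttachment:
        for l in self.ligands:
            if l.label == label:
                return l
        raise TopologyError(f"{self.name}: unknown ligand {label!r}")

    def module_of(self, ref) -> str:
        """Module id owning a residue index, a ligand label, or an atom.

        Accepts an ``int`` residue index, a ``str`` ligand label, or any
        object exposing ``residue_index``/``ligand`` attributes (an Atom).
        """
        if hasattr(ref, "residue_index") or hasattr(ref, "ligand"):
            lig = getattr(ref, "ligand", None)
            if lig is not None:
                return self.module_of(lig)
            return self.module_of(getattr(ref, "residue_index"))
        if isinstance(ref, str):
            return self.ligand(ref).module_id
        if isinstance(ref, int):
            try:
                return self._residue_module[ref]
            except KeyError:
                raise TopologyError(
                    f"{self.name}: no residue with index {ref}") from None
        raise TopologyError(f"cannot resolve module of {ref!r}")


def module_of(topology: ConjugateTopology, ref) -> str:
    """Functional alias for :meth:`ConjugateTopology.module_of`."""
    return topology.module_of(ref)


# ---------------------------------------------------------------------------
# Declarative design records
# ---------------------------------------------------------------------------

def load_ligand_registry() -> dict[str, LigandTemplate]:
    """Ligand templates bundled with the package, keyed by name."""
    raw = yaml.safe_load(_data.read_text("ligands.yaml"))
    registry: dict[str, LigandTemplate] = {}
    for entry in raw["ligands"]:
        atoms = tuple(
            LigandAtom(
                name=a["name"],
                element=a["element"],
                xyz=tuple(float(v) for v in a["xyz"]),
                apolar=bool(a.get("apolar", False)),
                donor=bool(a.get("donor", False)),
                acceptor=bool(a.get("acceptor", False)),
                charge_group=a.get("charge_group"),
                charge_sign=a.get("charge"),
            )
            for a in entry["atoms"]
        )
        tpl = LigandTemplate(
            name=entry["name"],
            resname=entry["resname"],
            atoms=atoms,
            bonds=tuple((b[0], b[1]) for b in entry.get("bonds", [])),
            attachment=entry["attachment"],
            description=entry.get("description", ""),
        )
        if tpl.name in registry:
            raise TopologyError(f"duplicate ligand template {tpl.name!r}")
        registry[tpl.name] = tpl
    return registry


def parse_conjugate_spec(
    spec_text: str | dict,
    ligand_registry: dict[str, LigandTemplate] | None = None,
    allow_nonstandard_asm: bool = False,
) -> ConjugateTopology:
    """Parse one declarative design record (YAML text or mapping).

    The record lists module segments in N->C order with sequences, plus
    ligand attachments.  Residues are numbered contiguously from 1 at the
    N terminus.  Segments may carry explicit ``start``/``end`` indices; if
    present they must reproduce the contiguous disjoint numbering.
    """
    record = yaml.safe_load(spec_text) if isinstance(spec_text, str) else spec_text
    if ligand_registry is None:
        ligand_registry = load_ligand_registry()
    name = record["name"]

    residues: list[Residue] = []
    spans: dict[str, dict] = {}
    pos = 1
    for seg in record.get("segments", []):
        mod = seg["module"]
        if mod not in MODULE_IDS:
            raise TopologyError(f"{name}: unknown module id {mod!r}")
        seq = seg["sequence"].strip().upper()
        bad = [c for c in seq if c not in STANDARD_AA]
        if bad:
            raise TopologyError(f"{name}: non-standard residue codes {bad} in {mod}")
        start, end = pos, pos + len(seq) - 1
        if "start" in seg or "end" in seg:
            if int(seg.get("start", start)) != start or int(seg.get("end", end)) != end:
                raise TopologyError(
                    f"{name}: segment {mod} declares span "
                    f"{seg.get('start')}-{seg.get('end')} but contiguous N->C "
                    f"numbering requires {start}-{end} (overlapping or gapped spans)")
        if mod == "ASM" and seq != ASM_SEQUENCE and not allow_nonstandard_asm:
            raise TopologyError(
                f"{name}: ASM sequence {seq!r} differs from {ASM_SEQUENCE!r} "
                "(pass allow_nonstandard_asm=True to override)")
        if mod in spans:
            raise TopologyError(f"{name}: module {mod} appears twice")
        for c in seq:
            residues.append(Residue(index=pos, code=c))
            pos += 1
        spans[mod] = {"start": start, "end": end, "ligands": []}

    if not residues:
        raise TopologyError(f"{name}: design has no residues")
    residues[0] = replace(residues[0], is_N_terminal=True)
    residues[-1] = replace(residues[-1], is_C_terminal=True)

    attachments: list[LigandAttachment] = []
    counts: dict[str, int] = {}
    for lig in record.get("ligands", []):
        tname = lig["template"]
        if tname not in ligand_registry:
            raise TopologyError(f"{name}: unknown ligand template {tname!r}")
        counts[tname] = counts.get(tname, 0) + 1
        label = tname if counts[tname] == 1 else f"{tname}{counts[tname]}"
        mod = lig["module"]
        if mod not in MODULE_IDS:
            raise TopologyError(f"{name}: unknown module id {mod!r} for ligand {label}")
        attachments.append(
            LigandAttachment(
                label=label,
                template=ligand_registry[tname],
                anchor=int(lig["anchor"]),
                site=lig.get("site", "side_chain"),
                module_id=mod,
            ))
        spans.setdefault(mod, {"start": None, "end": None, "ligands": []})
        spans[mod]["ligands"].append(label)

    span_objs = tuple(
        ModuleSpan(module_id=m, start=d["start"], end=d["end"], ligands=tuple(d["ligands"]))
        for m, d in spans.items()
    )
    motif = record.get("cleavage_motif")
    rule = CleavageRule(motif=motif) if motif else None
    return ConjugateTopology(
        name=name, residues=tuple(residues), spans=span_objs,
        ligands=tuple(attachments), cleavage_rule=rule)


# ---------------------------------------------------------------------------
# Built-in design registry
# ---------------------------------------------------------------------------

def _raw_designs() -> dict[str, dict]:
    raw = yaml.safe_load(_data.read_text("designs.yaml"))
    return {d["name"]: d for d in raw["designs"]}


def available_designs() -> list[str]:
    return list(_raw_designs())


def load_design(name: str) -> ConjugateTopology:
    """Instantiate a built-in design (Palpha, Pbeta, Pbeta_R4C, ...)."""
    designs = _raw_designs()
    if name not in designs:
        raise TopologyError(
            f"unknown design {name!r}; available: {', '.join(designs)}")
    return parse_conjugate_spec(designs[name])


def design_default_motif(name: str) -> str:
    """Default backbone motif (helix/hairpin) declared for a built-in design."""
    designs = _raw_designs()
    if name not in designs:
        raise TopologyError(f"unknown design {name!r}")
    return designs[name].get("default_motif", "extended")


# ---------------------------------------------------------------------------
# Cleavage
# ---------------------------------------------------------------------------

def cleave(topology: ConjugateTopology, rule: CleavageRule | None = None
           ) -> list[ConjugateTopology]:
    """Cut the chain C-terminal to every occurrence of the recognition motif.

    Products are returned N->C; ligands travel with their anchor residue and
    module spans are clipped and re-indexed.  A topology without the motif
    yields a single product identical to the input.
    """
    if rule is None:
        rule = topology.cleavage_rule or CleavageRule()
    seq = topology.sequence
    cuts: list[int] = []       # cut after this 1-based residue index
    startpos = 0
    while True:
        hit = seq.find(rule.motif, startpos)
        if hit < 0:
            break
        cuts.append(hit + len(rule.motif))
        startpos = hit + len(rule.motif)
    bounds = [0] + [c for c in cuts if c < len(seq)] + [len(seq)]
    if len(bounds) == 2:
        return [topology]

    products: list[ConjugateTopology] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        shift = lo
        res = []
        for r in topology.residues[lo:hi]:
            res.append(Residue(
                index=r.index - shift, code=r.code,
                is_N_terminal=(r.index - shift == 1),
                is_C_terminal=(r.index == hi),
            ))
        keep_ligs = [l for l in topology.ligands if lo < l.anchor <= hi]
        new_ligs = tuple(
            replace(l, anchor=l.anchor - shift) for l in keep_ligs)
        new_spans = []
        for s in topology.spans:
            ligs = tuple(lab for lab in s.ligands
                         if lo < topology.ligand(lab).anchor <= hi)
            if s.start is not None:
                a, b = max(s.start, lo + 1), min(s.end, hi)
                if a <= b:
                    new_spans.append(ModuleSpan(s.module_id, a - shift, b - shift, ligs))
                    continue
            if ligs:
                new_spans.append(ModuleSpan(s.module_id, None, None, ligs))
        products.append(ConjugateTopology(
            name=f"{topology.name}[{lo + 1}-{hi}]",
            residues=tuple(res),
            spans=tuple(new_spans),
            ligands=new_ligs,
            cleavage_rule=rule,
        ))
    return products
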
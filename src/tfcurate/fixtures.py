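"""Bundled ontology subgraph and synthetic curation-record generator.

Ships the hand-encoded GO subgraph that DbTF curation operates on, so the
engine works with no ontology download, and generates reproducible
synthetic curation records so every other module is testable end to end.

Term provenance: terms marked ``protocol`` are named explicitly in the
curation guidelines this engine encodes; terms marked ``go_release`` are
not, and were sourced from a GO release
snapshot contemporary with it (2013-02-16) — in particular the
positive/negative regulation children of GO:0006357 (GO:0045944 /
GO:0000122), the negative composite activity terms (GO:0001078 /
GO:0001206), the generic sequence-specific activity parent GO:0003700 and
the TF-binding branch (GO:0008134, GO:0001085, GO:0000989, GO:0001190,
GO:0001191).  The mapping of regulatory-region binding with unknown RNAPII
dependence onto GO:0003700 is provisional (no explicit rule exists for it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .evidence import AssayEvidence, ConfigurationError
from .ontology import OntologyGraph, OntologyTerm, Relation
from .workflow import CurationRecord

# -- bundled curation subgraph ---------------------------------------------

# (term_id, name, namespace, provenance)
_PANEL_A_TERMS = [
    # yellow: sequence-specific DNA binding MF terms
    ("GO:0043565", "sequence-specific DNA binding", "molecular_function", "protocol"),
    ("GO:0000976", "transcription regulatory region sequence-specific DNA binding", "molecular_function", "protocol"),
    ("GO:0000977", "RNA polymerase II regulatory region sequence-specific DNA binding", "molecular_function", "protocol"),
    ("GO:0000978", "RNA polymerase II core promoter proximal region sequence-specific DNA binding", "molecular_function", "protocol"),
    ("GO:0000980", "RNA polymerase II distal enhancer sequence-specific DNA binding", "molecular_function", "protocol"),
    # blue: transcription regulation BP terms
    ("GO:0006355", "regulation of transcription, DNA-dependent", "biological_process", "go_release"),
    ("GO:0006357", "regulation of transcription from RNA polymerase II promoter", "biological_process", "protocol"),
    ("GO:0045944", "positive regulation of transcription from RNA polymerase II promoter", "biological_process", "go_release"),
    ("GO:0000122", "negative regulation of transcription from RNA polymerase II promoter", "biological_process", "go_release"),
    # green: sequence-specific DbTF activity MF terms
    ("GO:0003700", "sequence-specific DNA binding transcription factor activity", "molecular_function", "go_release"),
    ("GO:0000981", "sequence-specific DNA binding RNA polymerase II transcription factor activity", "molecular_function", "protocol"),
    ("GO:0000982", "RNA polymerase II core promoter proximal region sequence-specific DNA binding transcription factor activity", "molecular_function", "protocol"),
    ("GO:0003705", "sequence-specific distal enhancer binding RNA polymerase II transcription factor activity", "molecular_function", "protocol"),
    ("GO:0001077", "RNA polymerase II core promoter proximal region sequence-specific DNA binding transcription factor activity involved in positive regulation of transcription", "molecular_function", "protocol"),
    ("GO:0001078", "RNA polymerase II core promoter proximal region sequence-specific DNA binding transcription factor activity involved in negative regulation of transcription", "molecular_function", "go_release"),
    ("GO:0001205", "RNA polymerase II distal enhancer sequence-specific DNA binding transcription factor activity involved in positive regulation of transcription", "molecular_function", "protocol"),
    ("GO:0001206", "RNA polymerase II distal enhancer sequence-specific DNA binding transcription factor activity involved in negative regulation of transcription", "molecular_function", "go_release"),
]

_PANEL_A_RELATIONS = [
    # yellow is_a ladder
    ("GO:0000976", "is_a", "GO:0043565"),
    ("GO:0000977", "is_a", "GO:0000976"),
    ("GO:0000978", "is_a", "GO:0000977"),
    ("GO:0000980", "is_a", "GO:0000977"),
    # blue is_a ladder
    ("GO:0006357", "is_a", "GO:0006355"),
    ("GO:0045944", "is_a", "GO:0006357"),
    ("GO:0000122", "is_a", "GO:0006357"),
    # green is_a ladder
    ("GO:0000981", "is_a", "GO:0003700"),
    ("GO:0000982", "is_a", "GO:0000981"),
    ("GO:0003705", "is_a", "GO:0000981"),
    ("GO:0001077", "is_a", "GO:0000982"),
    ("GO:0001078", "is_a", "GO:0000982"),
    ("GO:0001205", "is_a", "GO:0003705"),
    ("GO:0001206", "is_a", "GO:0003705"),
    # green has_part yellow (the required binding function)
    ("GO:0003700", "has_part", "GO:0043565"),
    ("GO:0000981", "has_part", "GO:0000977"),
    ("GO:0000982", "has_part", "GO:0000978"),
    ("GO:0003705", "has_part", "GO:0000980"),
    ("GO:0001077", "has_part", "GO:0000978"),
    ("GO:0001078", "has_part", "GO:0000978"),
    ("GO:0001205", "has_part", "GO:0000980"),
    ("GO:0001206", "has_part", "GO:0000980"),
    # green part_of blue (the regulation process the activity serves)
    ("GO:0003700", "part_of", "GO:0006355"),
    ("GO:0000981", "part_of", "GO:0006357"),
    ("GO:0000982", "part_of", "GO:0006357"),
    ("GO:0003705", "part_of", "GO:0006357"),
    ("GO:0001077", "part_of", "GO:0045944"),
    ("GO:0001078", "part_of", "GO:0000122"),
    ("GO:0001205", "part_of", "GO:0045944"),
    ("GO:0001206", "part_of", "GO:0000122"),
]

_PANEL_B_TERMS = [
    # yellow: TF binding MF terms
    ("GO:0008134", "transcription factor binding", "molecular_function", "go_release"),
    ("GO:0001085", "RNA polymerase II transcription factor binding", "molecular_function", "go_release"),
    # blue: shared transcription regulation BP terms
    ("GO:0006355", "regulation of transcription, DNA-dependent", "biological_process", "go_release"),
    ("GO:0006357", "regulation of transcription from RNA polymerase II promoter", "biological_process", "protocol"),
    ("GO:0045944", "positive regulation of transcription from RNA polymerase II promoter", "biological_process", "go_release"),
    ("GO:0000122", "negative regulation of transcription from RNA polymerase II promoter", "biological_process", "go_release"),
    # green: TF-binding TF activity MF terms
    ("GO:0000989", "transcription factor binding transcription factor activity", "molecular_function", "go_release"),
    ("GO:0001076", "RNA polymerase II transcription factor binding transcription factor activity", "molecular_function", "protocol"),
    ("GO:0001190", "RNA polymerase II transcription factor binding transcription factor activity involved in positive regulation of transcription", "molecular_function", "go_release"),
    ("GO:0001191", "RNA polymerase II transcription factor binding transcription factor activity involved in negative regulation of transcription", "molecular_function", "go_release"),
]

_PANEL_B_RELATIONS = [
    ("GO:0001085", "is_a", "GO:0008134"),
    ("GO:0006357", "is_a", "GO:0006355"),
    ("GO:0045944", "is_a", "GO:0006357"),
    ("GO:0000122", "is_a", "GO:0006357"),
    ("GO:0001076", "is_a", "GO:0000989"),
    ("GO:0001190", "is_a", "GO:0001076"),
    ("GO:0001191", "is_a", "GO:0001076"),
    ("GO:0000989", "has_part", "GO:0008134"),
    ("GO:0001076", "has_part", "GO:0001085"),
    ("GO:0001190", "has_part", "GO:0001085"),
    ("GO:0001191", "has_part", "GO:0001085"),
    ("GO:0000989", "part_of", "GO:0006355"),
    ("GO:0001076", "part_of", "GO:0006357"),
    ("GO:0001190", "part_of", "GO:0045944"),
    ("GO:0001191", "part_of", "GO:0000122"),
]


def _build_graph(terms, relations) -> OntologyGraph:
    graph = OntologyGraph()
    for term_id, name, namespace, _ in terms:
        graph.add_term(OntologyTerm(term_id, name, namespace))
    for subject, rel_type, obj in relations:
        graph.add_relation(Relation(subject, rel_type, obj))
    graph.validate()
    return graph


@dataclass(frozen=True)
class SubgraphFixture:
    """The two curation subgraphs plus per-term provenance notes."""

    panel_a: OntologyGraph
    panel_b: OntologyGraph
    provenance: Mapping[str, str]

    def combined(self) -> OntologyGraph:
        """Union of both panels as one graph (blue terms are shared)."""
        terms = {t[0]: t for t in _PANEL_A_TERMS + _PANEL_B_TERMS}
        relations = sorted(set(_PANEL_A_RELATIONS + _PANEL_B_RELATIONS))
        return _build_graph(terms.values(), relations)


def figure1_subgraph() -> SubgraphFixture:
    """The bundled curation subgraph; deterministic and stable across calls."""
    provenance = {t[0]: t[3] for t in _PANEL_A_TERMS + _PANEL_B_TERMS}
    return SubgraphFixture(
        panel_a=_build_graph(_PANEL_A_TERMS, _PANEL_A_RELATIONS),
        panel_b=_build_graph(_PANEL_B_TERMS, _PANEL_B_RELATIONS),
        provenance=provenance,
    )


# -- generator-side ground truth -------------------------------------------
#
# Frozen lookup of the expected composite term per (granularity, direction);
# intentionally a flat table, independent of the constraint search the
# inference engine performs, so end-to-end recovery is a real check.

_DNA_COMPOSITE_LOOKUP: Mapping[tuple[str, str], tuple[str, ...]] = {
    ("sequence_specific", "unspecified"): ("GO:0003700",),
    ("sequence_specific", "positive"): ("GO:0003700",),
    ("sequence_specific", "negative"): ("GO:0003700",),
    ("sequence_specific", "both"): ("GO:0003700",),
    ("regulatory_region", "unspecified"): ("GO:0003700",),
    ("regulatory_region", "positive"): ("GO:0003700",),
    ("regulatory_region", "negative"): ("GO:0003700",),
    ("regulatory_region", "both"): ("GO:0003700",),
    ("rnapii_regulatory", "unspecified"): ("GO:0000981",),
    ("rnapii_regulatory", "positive"): ("GO:0000981",),
    ("rnapii_regulatory", "negative"): ("GO:0000981",),
    ("rnapii_regulatory", "both"): ("GO:0000981",),
    ("proximal", "unspecified"): ("GO:0000982",),
    ("proximal", "positive"): ("GO:0001077",),
    ("proximal", "negative"): ("GO:0001078",),
    ("proximal", "both"): ("GO:0001077", "GO:0001078"),
    ("distal", "unspecified"): ("GO:0003705",),
    ("distal", "positive"): ("GO:0001205",),
    ("distal", "negative"): ("GO:0001206",),
    ("distal", "both"): ("GO:0001205", "GO:0001206"),
}

_TF_COMPOSITE_LOOKUP: Mapping[str, tuple[str, ...]] = {
    "unspecified": ("GO:0001076",),
    "positive": ("GO:0001190",),
    "negative": ("GO:0001191",),
    "both": ("GO:0001190", "GO:0001191"),
}


@dataclass(frozen=True)
class RecordTruth:
    """Planted ground truth for one generated record."""

    qualifies: bool
    cross_paper: bool
    expected_composites: tuple[str, ...]
    expected_ic: int


# -- synthetic record generator --------------------------------------------

#: admissible DNA-binding evidence templates: (assay, variant, flags)
_ADMISSIBLE_DNA = [
    ("emsa", "purified", frozenset()),
    ("emsa", "ectopic_extract", frozenset()),
    ("emsa", "mutant_extract", frozenset()),
    ("emsa", "native_extract", frozenset({"mutant_probe_competition", "wt_probe_competition"})),
    ("emsa_supershift", "native_extract", frozenset({"specific_antibody"})),
    ("footprinting", "not_applicable", frozenset()),
    ("dnase_footprint", "not_applicable", frozenset()),
    ("selex", "not_applicable", frozenset()),
    ("pull_down", "not_applicable", frozenset()),
    ("southwestern_blot", "not_applicable", frozenset()),
    ("xray_crystallography", "not_applicable", frozenset({"dna_cocrystal"})),
]

_TF_BINDING_TEMPLATES = [
    ("two_hybrid", True),
    ("coimmunoprecipitation", True),
    ("coimmunoprecipitation", False),
    ("copurification", True),
]

_REG_IDENTIFICATIONS = ["ectopic_wt", "ectopic_mut", "knock_down", "knock_out"]
_REG_IDENTIFICATION_WEIGHTS = [0.5, 0.15, 0.2, 0.15]


@dataclass(frozen=True)
class RecordProfile:
    """Mixture weights for the synthetic record generator.

    Defaults reflect a realistic small-scale curation batch: mostly human
    studies with some mouse/rat, a minority of out-of-scope or unidentified
    species, a sizeable fraction of evidence split across two papers, and a
    tail of dismissible native-extract gel shifts.
    """

    species_weights: Mapping[str, float] = field(default_factory=lambda: {
        "taxon:9606": 0.50,   # human
        "taxon:10090": 0.22,  # mouse
        "taxon:10116": 0.13,  # rat
        "taxon:7227": 0.08,   # out of scope (fly)
        "": 0.07,             # species unidentifiable
    })
    granularity_weights: Mapping[str, float] = field(default_factory=lambda: {
        "sequence_specific": 0.10,
        "regulatory_region": 0.10,
        "rnapii_regulatory": 0.25,
        "proximal": 0.30,
        "distal": 0.25,
    })
    direction_weights: Mapping[str, float] = field(default_factory=lambda: {
        "unspecified": 0.35,
        "positive": 0.30,
        "negative": 0.20,
        "both": 0.15,
    })
    p_cross_paper: float = 0.30
    p_dismissible_binding: float = 0.15
    p_inadmissible_regulation: float = 0.10
    p_tf_binding: float = 0.20
    p_contributes_to: float = 0.10
    p_target_genes: float = 0.50
    p_tg_mrna_readout: float = 0.15

    def _validated(self, name: str, weights: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
        keys = list(weights)
        values = np.asarray([weights[k] for k in keys], dtype=float)
        if (values < 0).any():
            raise ConfigurationError(f"{name} weights must be non-negative")
        total = values.sum()
        if total <= 0:
            raise ConfigurationError(f"{name} weights must not sum to zero")
        return keys, values / total

    def __post_init__(self) -> None:
        for name in ("species_weights", "granularity_weights", "direction_weights"):
            self._validated(name, getattr(self, name))
        for name in (
            "p_cross_paper", "p_dismissible_binding", "p_inadmissible_regulation",
            "p_tf_binding", "p_contributes_to", "p_target_genes", "p_tg_mrna_readout",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be a probability, got {value}")


def _choice(rng: np.random.Generator, profile: RecordProfile, name: str) -> str:
    keys, probs = profile._validated(name, getattr(profile, name))
    return keys[rng.choice(len(keys), p=probs)]


def generate_records_with_truth(
    n: int,
    profile: RecordProfile | None = None,
    seed: int = 0,
) -> tuple[list[CurationRecord], list[RecordTruth]]:
    """Generate ``n`` internally consistent records plus planted ground truth."""
    if n < 0:
        raise ValueError("n must be >= 0")
    profile = profile or RecordProfile()
    rng = np.random.default_rng(seed)
    records: list[CurationRecord] = []
    truths: list[RecordTruth] = []
    for i in range(n):
        species = _choice(rng, profile, "species_weights")
        granularity = _choice(rng, profile, "granularity_weights")
        direction = _choice(rng, profile, "direction_weights")
        dismissible = rng.random() < profile.p_dismissible_binding
        reg_inadmissible = rng.random() < profile.p_inadmissible_regulation
        cross_paper = rng.random() < profile.p_cross_paper
        with_tf = rng.random() < profile.p_tf_binding
        contributes = rng.random() < profile.p_contributes_to
        with_targets = rng.random() < profile.p_target_genes

        binding_ref = f"PMID:{9_000_000 + 10 * i}"
        regulation_ref = f"PMID:{9_000_000 + 10 * i + 1}" if cross_paper else binding_ref

        if dismissible:
            dna = (AssayEvidence(assay="emsa", variant="native_extract", reference=binding_ref),)
        else:
            assay, variant, flags = _ADMISSIBLE_DNA[rng.integers(len(_ADMISSIBLE_DNA))]
            dna = (AssayEvidence(assay=assay, variant=variant, verification=flags, reference=binding_ref),)

        tf_evidence: tuple = ()
        if with_tf:
            assay, with_partner = _TF_BINDING_TEMPLATES[rng.integers(len(_TF_BINDING_TEMPLATES))]
            partner = f"FAKEDB:PARTNER{i:05d}" if with_partner else None
            tf_evidence = ((AssayEvidence(assay=assay, reference=binding_ref), partner),)

        corroboration = False
        entry_directions = ("positive", "negative") if direction == "both" else (direction,)
        regulation = []
        for entry_direction in entry_directions:
            if reg_inadmissible:
                regulation.append((
                    AssayEvidence(assay="reporter_gene", reference=regulation_ref),
                    "native", "reporter_wt_tfbs", entry_direction,
                ))
                continue
            identification = _REG_IDENTIFICATIONS[
                rng.choice(len(_REG_IDENTIFICATIONS), p=_REG_IDENTIFICATION_WEIGHTS)
            ]
            if rng.random() < profile.p_tg_mrna_readout:
                assay_name, readout = "tg_mrna_expression", "tg_mrna"
                if identification in ("knock_down", "knock_out"):
                    corroboration = True  # required for endogenous-mRNA readouts
            else:
                assay_name, readout = "reporter_gene", "reporter_wt_tfbs"
            regulation.append((
                AssayEvidence(assay=assay_name, reference=regulation_ref),
                identification, readout, entry_direction,
            ))

        targets = tuple(
            f"FAKEGENE:G{i:05d}_{k}" for k in range(int(rng.integers(1, 4)))
        ) if with_targets else ()

        records.append(CurationRecord(
            gene_product=("FAKEDB", f"SYNTF{i:05d}", f"syntf{i}"),
            taxon=species,
            paper_refs=tuple(sorted({binding_ref, regulation_ref})),
            binding_granularity=granularity,
            dna_binding_evidence=dna,
            tf_binding_evidence=tf_evidence,
            regulation_evidence=tuple(regulation),
            contributes_to=contributes,
            binding_corroboration=corroboration,
            target_genes=targets,
        ))

        expected: tuple[str, ...] = ()
        truth_direction = direction if not reg_inadmissible else None
        if truth_direction is not None:
            if not dismissible:
                expected += _DNA_COMPOSITE_LOOKUP[(granularity, truth_direction)]
            if with_tf:
                expected += _TF_COMPOSITE_LOOKUP[truth_direction]
        qualifies = bool(expected)
        # one IC record per cross-paper inference = per (binding mode x
        # regulation direction); two directions can land on the same
        # composite term (distinct with/from) at coarse granularities
        n_modes = int(not dismissible) + int(with_tf)
        expected_ic = n_modes * len(entry_directions) if (qualifies and cross_paper) else 0
        truths.append(RecordTruth(
            qualifies=qualifies,
            cross_paper=cross_paper,
            expected_composites=expected,
            expected_ic=expected_ic,
        ))
    return records, truths


def generate_records(
    n: int,
    profile: RecordProfile | None = None,
    seed: int = 0,
) -> list[CurationRecord]:
    """Generate ``n`` synthetic curation records (reproducible given seed)."""
    records, _ = generate_records_with_truth(n, profile, seed)
    return records
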
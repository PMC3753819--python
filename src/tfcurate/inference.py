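"""Composite transcription-factor-activity inference.

A DbTF annotation to a composite "TF activity" molecular-function term is
never made directly from one experiment.  It is inferred from two separately
evidenced annotations — a binding annotation (MF) and a transcription
regulation annotation (BP) — because the activity terms are defined in GO by
exactly those two links: ``has_part`` a binding function and ``part_of`` a
regulation process.

The engine searches the ontology subgraph for the most specific activity
term whose requirements are fully covered by the evidence: every has_part
target (direct or inherited down is_a) must be at or above the evidenced
binding term, and every part_of target at or above the evidenced regulation
term.  That "at or above" direction is what stops over-claiming — evidence
for regulatory-region binding can never yield a promoter-proximal activity
term.

Evidence codes propagate with the annotations: when binding and regulation
come from the same paper the composite inherits their codes (possibly as
two records when the codes differ); when they come from different papers
the composite is an IC (inferred by curator) record citing GO_REF:0000036
with the two contributing GO IDs in with/from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

from .evidence import classify_dna_binding, classify_regulation, classify_tf_binding
from .gaf import GO_REF_IC, Annotation
from .ontology import OntologyGraph

if TYPE_CHECKING:  # pragma: no cover
    from .workflow import CurationRecord

logger = logging.getLogger("tfcurate.inference")

MODES = frozenset({"dna", "tf_binding", "dna_contributes"})
GRANULARITIES = frozenset({
    "sequence_specific", "regulatory_region", "rnapii_regulatory",
    "proximal", "distal", "tf_generic",
})
DIRECTIONS = frozenset({"unspecified", "positive", "negative", "both"})

#: binding granularity -> MF binding term annotated as evidence
GRANULARITY_TERMS: Mapping[str, str] = {
    "sequence_specific": "GO:0043565",   # sequence-specific DNA binding
    "regulatory_region": "GO:0000976",   # transcription regulatory region ssDNA binding
    "rnapii_regulatory": "GO:0000977",   # RNAP II regulatory region ssDNA binding
    "proximal": "GO:0000978",            # RNAP II core promoter proximal region
    "distal": "GO:0000980",              # RNAP II distal enhancer
    "tf_generic": "GO:0001085",          # RNAP II transcription factor binding
}

#: regulation direction -> BP term(s) annotated as evidence
DIRECTION_TERMS: Mapping[str, tuple[str, ...]] = {
    "unspecified": ("GO:0006357",),
    "positive": ("GO:0045944",),
    "negative": ("GO:0000122",),
    "both": ("GO:0045944", "GO:0000122"),
}


class InferenceError(Exception):
    """Base class for inference failures."""


class InferenceRefusedError(InferenceError):
    """Inputs are not an admissible binding/regulation pair."""


class NoRuleError(InferenceError):
    """No composite activity term in the graph satisfies the inputs."""


class RuleViolationError(InferenceError):
    """Evidence-code combination forbidden by the propagation rules."""


@dataclass(frozen=True)
class BindingClass:
    """The binding half of a composite inference: mode + granularity."""

    mode: str
    granularity: str
    go_id: str = ""

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise InferenceRefusedError(f"unknown binding mode {self.mode!r}")
        if self.granularity not in GRANULARITIES:
            raise InferenceRefusedError(f"unknown binding granularity {self.granularity!r}")
        if (self.mode == "tf_binding") != (self.granularity == "tf_generic"):
            raise InferenceRefusedError(
                f"mode {self.mode!r} incompatible with granularity {self.granularity!r}"
            )
        if not self.go_id:
            object.__setattr__(self, "go_id", GRANULARITY_TERMS[self.granularity])
        elif self.go_id != GRANULARITY_TERMS[self.granularity]:
            raise InferenceRefusedError(
                f"go_id {self.go_id} does not match granularity {self.granularity!r}"
            )


@dataclass(frozen=True)
class RegulationClass:
    """The regulation half of a composite inference: direction of effect."""

    direction: str

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise InferenceRefusedError(f"unknown regulation direction {self.direction!r}")

    @property
    def go_ids(self) -> tuple[str, ...]:
        return DIRECTION_TERMS[self.direction]


@dataclass(frozen=True)
class InferenceResult:
    """A composite TF-activity annotation plus its provenance."""

    composite_go_id: str
    evidence_code: str
    contributing: tuple[tuple[str, str, str], tuple[str, str, str]]  # (go_id, reference, code)
    with_from: tuple[str, ...] = ()
    references: tuple[str, ...] = ()
    qualifiers: tuple[str, ...] = ()


# -- constraint search -----------------------------------------------------

def activity_terms(graph: OntologyGraph) -> list[str]:
    """Composite-candidate MF terms: those defined by has_part + part_of links."""
    out = []
    for term_id, term in graph.terms.items():
        if term.namespace != "molecular_function":
            continue
        if graph.effective_targets(term_id, "has_part") and graph.effective_targets(term_id, "part_of"):
            out.append(term_id)
    return sorted(out)


def _satisfies(graph: OntologyGraph, candidate: str, binding_go: str, regulation_go: str) -> bool:
    """True iff every requirement of ``candidate`` is covered by the evidence."""
    binding_up = graph.ancestors(binding_go, {"is_a"}) | {binding_go}
    regulation_up = graph.ancestors(regulation_go, {"is_a"}) | {regulation_go}
    has_part = graph.effective_targets(candidate, "has_part")
    part_of = graph.effective_targets(candidate, "part_of")
    return all(h in binding_up for h in has_part) and all(p in regulation_up for p in part_of)


def infer_composite_term(
    binding: BindingClass,
    regulation: RegulationClass,
    graph: OntologyGraph,
) -> tuple[str, ...]:
    """Most specific composite activity term(s) for a binding/regulation pair.

    Returns one term per regulation direction (two when direction is
    ``both``).  Raises :class:`NoRuleError` when no activity term in the
    graph is consistent with the inputs.
    """
    if binding.go_id not in graph:
        raise NoRuleError(f"binding term {binding.go_id} absent from graph")
    candidates = activity_terms(graph)
    results: list[str] = []
    for regulation_go in regulation.go_ids:
        if regulation_go not in graph:
            raise NoRuleError(f"regulation term {regulation_go} absent from graph")
        satisfiers = [c for c in candidates if _satisfies(graph, c, binding.go_id, regulation_go)]
        if not satisfiers:
            raise NoRuleError(
                f"no activity term satisfies binding={binding.go_id} ({binding.granularity}), "
                f"regulation={regulation_go} ({regulation.direction})"
            )
        most_specific = [
            c for c in satisfiers
            if not any(o != c and graph.is_more_specific(o, c) for o in satisfiers)
        ]
        if len(most_specific) > 1:
            logger.warning(
                "multiple incomparable activity terms satisfy binding=%s regulation=%s: %s",
                binding.go_id, regulation_go, most_specific,
            )
        for term in most_specific:
            if term not in results:
                results.append(term)
    return tuple(results)


# -- evidence propagation --------------------------------------------------

_BINDING_CODES = frozenset({"IDA", "IMP", "IPI"})
_REGULATION_CODES = frozenset({"IDA", "IMP"})


def propagate_evidence(
    binding_ev: str,
    regulation_ev: str,
    same_reference: bool,
    binding_mode: str = "dna",
) -> list[tuple[str, str]]:
    """Evidence code(s) for the composite annotation.

    Returns ``(code, with_from_policy)`` pairs, policy one of ``none``,
    ``partner`` (IPI: interaction partner id) or ``go_ids`` (IC: the two
    contributing GO IDs).  Same-paper evidence transfers the contributing
    codes — two records when they differ; cross-paper evidence collapses to
    a single curator inference (IC).
    """
    if binding_ev not in _BINDING_CODES:
        raise RuleViolationError(f"binding evidence code must be one of {sorted(_BINDING_CODES)}")
    if regulation_ev not in _REGULATION_CODES:
        raise RuleViolationError(f"regulation evidence code must be one of {sorted(_REGULATION_CODES)}")
    if binding_ev == "IPI" and binding_mode not in ("tf_binding",):
        raise RuleViolationError("IPI applicable only for TF binding terms")
    if not same_reference:
        return [("IC", "go_ids")]
    if binding_ev == regulation_ev:
        return [(binding_ev, "none")]
    policy = "partner" if binding_ev == "IPI" else "none"
    return [(binding_ev, policy), (regulation_ev, "none")]


# -- record-level annotation building --------------------------------------

def _dedup_key(ann: Annotation) -> tuple:
    return (ann.go_id, ann.evidence_code, ann.references, ann.with_from, ann.qualifiers)


def build_annotations(
    record: "CurationRecord",
    graph: OntologyGraph,
    *,
    date: str = "20130216",
    assigned_by: str = "tfcurate",
    matrix: Mapping[tuple[str, str], str | None] | None = None,
) -> list[Annotation]:
    """All GAF annotations derivable from one curation record.

    Emits, in order: MF binding annotations (one per admissible binding
    evidence), BP regulation annotations (one per evidenced direction, with
    has_regulation_target extensions), then composite activity annotations
    for every admissible (binding mode x direction) pair.  Without both an
    admissible binding and an admissible regulation verdict the composite
    step is skipped — the two-part DbTF qualification criterion.
    """
    db, object_id, symbol = record.gene_product
    common = dict(
        db=db, object_id=object_id, symbol=symbol,
        taxon=record.taxon, date=date, assigned_by=assigned_by,
    )
    contributes = ("contributes_to",) if record.contributes_to else ()

    dna_ok: list[tuple] = []
    for ev in record.dna_binding_evidence:
        verdict = classify_dna_binding(ev)
        if verdict.admissible:
            dna_ok.append((ev, verdict))
        else:
            logger.info("%s: dismissed DNA-binding evidence (%s): %s", object_id, ev.assay, verdict.reason)
    tf_ok: list[tuple] = []
    for ev, partner in record.tf_binding_evidence:
        verdict = classify_tf_binding(ev, partner)
        if verdict.admissible:
            tf_ok.append((ev, partner, verdict))
        else:
            logger.info("%s: dismissed TF-binding evidence (%s): %s", object_id, ev.assay, verdict.reason)
    reg_ok: list[tuple] = []
    for ev, identification, readout, direction in record.regulation_evidence:
        verdict = classify_regulation(
            ev, identification, readout,
            binding_corroboration=record.binding_corroboration, matrix=matrix,
        )
        if verdict.admissible:
            reg_ok.append((ev, direction, verdict))
        else:
            logger.info("%s: dismissed regulation evidence (%s): %s", object_id, ev.assay, verdict.reason)

    annotations: list[Annotation] = []
    seen: set[tuple] = set()

    def emit(ann: Annotation) -> None:
        key = _dedup_key(ann)
        if key not in seen:
            seen.add(key)
            annotations.append(ann)

    # (a) MF binding annotations
    binding_go = GRANULARITY_TERMS[record.binding_granularity]
    for ev, verdict in dna_ok:
        emit(Annotation(
            **common, go_id=binding_go, aspect="F", qualifiers=contributes,
            references=(ev.reference,), evidence_code=verdict.evidence_code,
        ))
    for ev, partner, verdict in tf_ok:
        with_from = (partner,) if verdict.evidence_code == "IPI" else ()
        emit(Annotation(
            **common, go_id=GRANULARITY_TERMS["tf_generic"], aspect="F",
            references=(ev.reference,), evidence_code=verdict.evidence_code,
            with_from=with_from,
        ))

    # (b) BP regulation annotations, one per evidenced direction
    directions: list[str] = []
    reg_by_direction: dict[str, list[tuple]] = {}
    for ev, direction, verdict in reg_ok:
        if direction not in reg_by_direction:
            reg_by_direction[direction] = []
            directions.append(direction)
        reg_by_direction[direction].append((ev, verdict))
    extensions = tuple(("has_regulation_target", g) for g in record.target_genes)
    for direction in directions:
        ev, verdict = reg_by_direction[direction][0]
        emit(Annotation(
            **common, go_id=DIRECTION_TERMS[direction][0], aspect="P",
            references=(ev.reference,), evidence_code=verdict.evidence_code,
            extensions=extensions,
        ))

    # (c) composite activity annotations
    modes: list[tuple[str, list[tuple]]] = []
    if dna_ok:
        mode = "dna_contributes" if record.contributes_to else "dna"
        modes.append((mode, [(ev.reference, v.evidence_code, None) for ev, v in dna_ok]))
    if tf_ok:
        modes.append(("tf_binding", [(ev.reference, v.evidence_code, p) for ev, p, v in tf_ok]))
    if not modes or not reg_ok:
        if reg_ok or dna_ok or tf_ok:
            logger.info(
                "%s: DbTF qualification criteria not met (binding admissible: %s, "
                "regulation admissible: %s); no composite annotation",
                object_id, bool(modes), bool(reg_ok),
            )
        return annotations

    composites: list[Annotation] = []
    for mode, binding_pool in modes:
        granularity = "tf_generic" if mode == "tf_binding" else record.binding_granularity
        binding_class = BindingClass(mode=mode, granularity=granularity)
        for direction in directions:
            regulation_class = RegulationClass(direction=direction)
            terms = infer_composite_term(binding_class, regulation_class, graph)
            # prefer a same-paper binding/regulation pairing when one exists
            chosen = None
            for bref, bcode, partner in binding_pool:
                for ev, verdict in reg_by_direction[direction]:
                    if ev.reference == bref:
                        chosen = ((bref, bcode, partner), (ev.reference, verdict.evidence_code), True)
                        break
                if chosen:
                    break
            if chosen is None:
                bref, bcode, partner = binding_pool[0]
                ev, verdict = reg_by_direction[direction][0]
                chosen = ((bref, bcode, partner), (ev.reference, verdict.evidence_code), False)
            (bref, bcode, partner), (rref, rcode), same_reference = chosen
            regulation_go = DIRECTION_TERMS[direction][0]
            propagated = propagate_evidence(bcode, rcode, same_reference, binding_mode=mode)
            qualifiers = contributes if mode == "dna_contributes" else ()
            for term in terms:
                for code, policy in propagated:
                    if policy == "go_ids":
                        with_from = (binding_class.go_id, regulation_go)
                        references = (GO_REF_IC,)
                    elif policy == "partner":
                        with_from = (partner,) if partner else ()
                        references = (bref,)
                    else:
                        with_from = ()
                        references = (bref,)
                    composites.append(Annotation(
                        **common, go_id=term, aspect="F", qualifiers=qualifiers,
                        references=references, evidence_code=code, with_from=with_from,
                    ))

    # most-specific-wins dedup over is_a-comparable composites with equal evidence
    kept: list[Annotation] = []
    for ann in composites:
        superseded = any(
            other is not ann
            and other.evidence_code == ann.evidence_code
            and graph.is_more_specific(other.go_id, ann.go_id)
            for other in composites
        )
        if not superseded:
            kept.append(ann)
    for ann in kept:
        emit(ann)
    return annotations
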
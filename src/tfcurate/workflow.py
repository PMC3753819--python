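"""End-to-end DbTF curation workflow.

Pipeline over curation records: species filter (human/mouse/rat by
default) -> evidence admissibility and two-part DbTF qualification ->
annotation building -> GAF export, plus a lint mode for existing GAF files.

Also defines the package's own tab-separated curation-record exchange
format.  The source literature-curation process has no machine format —
curators read papers — so this schema is invented plumbing:

=====================  =====================================================
column                 content
=====================  =====================================================
db                     source database label for the gene product
object_id              gene-product accession
symbol                 gene symbol
taxon                  NCBI taxon ("taxon:9606"); empty = unidentifiable
refs                   pipe-separated reference ids (PMID:n / GO_REF:n)
granularity            binding granularity (sequence_specific ... distal)
contributes_to         0/1 — function exercised only within a complex
binding_corroboration  0/1 — direct-binding support for knock-out readouts
target_genes           pipe-separated target-gene ids (may be empty)
dna_binding            ';'-separated entries  assay/variant/flags/ref
                       (flags '+'-joined, '-' for none)
tf_binding             ';'-separated entries  assay/partner/ref ('-' = none)
regulation             ';'-separated entries
                       assay/identification/readout/direction/ref
=====================  =====================================================
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence, TextIO

from .evidence import (
    AssayEvidence,
    classify_dna_binding,
    classify_regulation,
    classify_tf_binding,
)
from .gaf import GO_REF_IC, Annotation, validate_annotation
from .inference import activity_terms, build_annotations
from .ontology import OntologyGraph

logger = logging.getLogger("tfcurate.workflow")

#: default curated species: human, mouse, rat (standard NCBI taxon ids)
DEFAULT_ALLOWED_TAXA = frozenset({"taxon:9606", "taxon:10090", "taxon:10116"})

ENTRY_DIRECTIONS = frozenset({"unspecified", "positive", "negative"})


class RecordError(Exception):
    """A curation record violates its invariants."""


@dataclass(frozen=True)
class CurationRecord:
    """Everything extracted from the literature about one gene product."""

    gene_product: tuple[str, str, str]  # (db, object_id, symbol)
    taxon: str
    paper_refs: tuple[str, ...]
    binding_granularity: str
    dna_binding_evidence: tuple[AssayEvidence, ...] = ()
    tf_binding_evidence: tuple[tuple[AssayEvidence, str | None], ...] = ()
    regulation_evidence: tuple[tuple[AssayEvidence, str, str, str], ...] = ()
    contributes_to: bool = False
    binding_corroboration: bool = False
    target_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.paper_refs:
            raise RecordError(f"{self.gene_product[1]}: paper_refs must be non-empty")
        refs = set(self.paper_refs)
        for ev in self.dna_binding_evidence:
            if ev.reference not in refs:
                raise RecordError(f"evidence reference {ev.reference} not in paper_refs")
        for ev, _ in self.tf_binding_evidence:
            if ev.reference not in refs:
                raise RecordError(f"evidence reference {ev.reference} not in paper_refs")
        for ev, _, _, direction in self.regulation_evidence:
            if ev.reference not in refs:
                raise RecordError(f"evidence reference {ev.reference} not in paper_refs")
            if direction not in ENTRY_DIRECTIONS:
                raise RecordError(
                    f"regulation evidence direction must be one of {sorted(ENTRY_DIRECTIONS)}; "
                    f"a record shows 'both' by carrying positive and negative entries"
                )


@dataclass
class PipelineConfig:
    """Tunable pipeline settings; defaults reproduce the curation protocol."""

    allowed_taxa: frozenset[str] = DEFAULT_ALLOWED_TAXA
    date: str = "20130216"
    assigned_by: str = "tfcurate"
    regulation_matrix: Mapping[tuple[str, str], str | None] | None = None


@dataclass
class PipelineReport:
    """Per-batch accounting; records_in == filtered_species + disqualified + annotated."""

    records_in: int = 0
    filtered_species: int = 0
    disqualified: int = 0
    annotated: int = 0
    evidence_counts: Counter = field(default_factory=Counter)
    ic_count: int = 0

    def to_dict(self) -> dict:
        return {
            "records_in": self.records_in,
            "filtered_species": self.filtered_species,
            "disqualified": self.disqualified,
            "annotated": self.annotated,
            "evidence_counts": dict(self.evidence_counts),
            "ic_count": self.ic_count,
        }


class Violation(NamedTuple):
    """One validation finding on a GAF record."""

    index: int
    rule: str
    message: str


# -- species filter --------------------------------------------------------

def normalize_taxon(taxon: str) -> str:
    taxon = taxon.strip()
    if taxon and not taxon.startswith("taxon:"):
        taxon = f"taxon:{taxon}"
    return taxon


def species_filter(record: CurationRecord, allowed_taxa: Iterable[str] = DEFAULT_ALLOWED_TAXA) -> bool:
    """True iff the record's species is identifiable and in the curated set."""
    taxon = normalize_taxon(record.taxon)
    if not taxon:
        logger.info("%s: rejected, species unidentifiable", record.gene_product[1])
        return False
    return taxon in set(allowed_taxa)


# -- qualification ---------------------------------------------------------

def qualify_dbtf(record: CurationRecord) -> tuple[bool, list[str]]:
    """Two-part qualification: admissible binding AND admissible regulation.

    A protein qualifies for a composite TF-activity annotation when at
    least one binding verdict (specific DNA binding, or TF binding for the
    TF-binding activity branch) and at least one transcription-regulation
    verdict are admissible.  The reasons list enumerates every dismissal.
    """
    reasons: list[str] = []
    dna_admissible = False
    for ev in record.dna_binding_evidence:
        verdict = classify_dna_binding(ev)
        if verdict.admissible:
            dna_admissible = True
        else:
            reasons.append(f"dismissed {ev.assay} ({ev.variant}): {verdict.reason}")
    tf_admissible = False
    for ev, partner in record.tf_binding_evidence:
        verdict = classify_tf_binding(ev, partner)
        if verdict.admissible:
            tf_admissible = True
        else:
            reasons.append(f"dismissed {ev.assay}: {verdict.reason}")
    regulation_admissible = False
    for ev, identification, readout, _ in record.regulation_evidence:
        verdict = classify_regulation(
            ev, identification, readout, binding_corroboration=record.binding_corroboration
        )
        if verdict.admissible:
            regulation_admissible = True
        else:
            reasons.append(f"dismissed {ev.assay} ({identification}/{readout}): {verdict.reason}")
    if not (dna_admissible or tf_admissible):
        reasons.append("no admissible binding evidence (DbTF criterion i: specific DNA binding)")
    if not regulation_admissible:
        reasons.append("no admissible transcription-regulation evidence (DbTF criterion ii)")
    return (dna_admissible or tf_admissible) and regulation_admissible, reasons


# -- pipeline --------------------------------------------------------------

def run_pipeline(
    records: Sequence[CurationRecord],
    graph: OntologyGraph,
    config: PipelineConfig | None = None,
) -> tuple[list[Annotation], PipelineReport]:
    """Batch curation: filter, qualify, annotate, account.

    Per-record failures are logged and isolated; they never abort the batch.
    Output is deterministic given input order (annotations within a record
    ordered binding -> regulation -> composite).
    """
    cfg = config or PipelineConfig()
    report = PipelineReport(records_in=len(records))
    annotations: list[Annotation] = []
    for record in records:
        if not species_filter(record, cfg.allowed_taxa):
            report.filtered_species += 1
            continue
        try:
            qualifies, reasons = qualify_dbtf(record)
            record_annotations = build_annotations(
                record, graph,
                date=cfg.date, assigned_by=cfg.assigned_by, matrix=cfg.regulation_matrix,
            )
        except Exception:
            logger.exception("%s: record failed; skipping", record.gene_product[1])
            report.disqualified += 1
            continue
        if qualifies:
            report.annotated += 1
        else:
            report.disqualified += 1
            for reason in reasons:
                logger.info("%s: %s", record.gene_product[1], reason)
        annotations.extend(record_annotations)
    for ann in annotations:
        report.evidence_counts[ann.evidence_code] += 1
    report.ic_count = report.evidence_counts.get("IC", 0)
    return annotations, report


# -- GAF lint --------------------------------------------------------------

def _is_tf_binding_related(graph: OntologyGraph, go_id: str) -> bool:
    """True iff a term is a TF-binding MF term or an activity defined on one."""
    tf_binding_root = "GO:0008134"
    if go_id not in graph:
        return False
    lineage = graph.ancestors(go_id, {"is_a"}) | {go_id}
    if tf_binding_root in lineage:
        return True
    for part in graph.effective_targets(go_id, "has_part"):
        if tf_binding_root in (graph.ancestors(part, {"is_a"}) | {part}):
            return True
    return False


def validate_gaf(annotations: Sequence[Annotation], graph: OntologyGraph) -> list[Violation]:
    """Lint a set of annotations against the curation rules.

    Flags composite TF-activity annotations lacking same-object binding and
    regulation support, malformed IC records, IPI on DNA-binding terms,
    contributes_to outside aspect F and aspect/namespace mismatches.
    """
    violations: list[Violation] = []
    composite_terms = set(activity_terms(graph))
    by_object: dict[tuple[str, str], list[Annotation]] = {}
    for ann in annotations:
        by_object.setdefault((ann.db, ann.object_id), []).append(ann)

    for index, ann in enumerate(annotations):
        for problem in validate_annotation(ann, graph):
            violations.append(Violation(index, "record_invariant", problem))
        if ann.evidence_code == "IC":
            if GO_REF_IC not in ann.references:
                violations.append(Violation(index, "ic_reference", f"IC record lacks {GO_REF_IC}"))
            if len(ann.with_from) < 2:
                violations.append(Violation(
                    index, "ic_with_from", "IC record must carry the two contributing GO IDs"
                ))
        if ann.evidence_code == "IPI" and not _is_tf_binding_related(graph, ann.go_id):
            violations.append(Violation(
                index, "ipi_scope", f"IPI applicable only for TF binding terms, not {ann.go_id}"
            ))
        if "contributes_to" in ann.qualifiers and ann.aspect != "F":
            violations.append(Violation(
                index, "contributes_to_aspect", "contributes_to only valid on aspect F"
            ))
        if ann.go_id in composite_terms:
            siblings = by_object[(ann.db, ann.object_id)]
            binding_support = False
            regulation_support = False
            has_part = graph.effective_targets(ann.go_id, "has_part")
            part_of = graph.effective_targets(ann.go_id, "part_of")
            for other in siblings:
                if other is ann or other.go_id not in graph:
                    continue
                lineage = graph.ancestors(other.go_id, {"is_a"}) | {other.go_id}
                if other.aspect == "F" and other.go_id not in composite_terms:
                    if all(h in lineage for h in has_part):
                        binding_support = True
                if other.aspect == "P":
                    if all(p in lineage for p in part_of):
                        regulation_support = True
            if not (binding_support and regulation_support):
                violations.append(Violation(
                    index, "composite_support",
                    f"composite activity annotation {ann.go_id} lacks same-object "
                    f"binding+regulation support (DbTF qualification criteria)",
                ))
    return violations


# -- record TSV I/O --------------------------------------------------------

RECORD_COLUMNS = [
    "db", "object_id", "symbol", "taxon", "refs", "granularity",
    "contributes_to", "binding_corroboration", "target_genes",
    "dna_binding", "tf_binding", "regulation",
]


def _parse_flags(token: str) -> frozenset[str]:
    return frozenset() if token in ("", "-") else frozenset(token.split("+"))


def _record_from_row(cols: list[str], lineno: int) -> CurationRecord:
    row = dict(zip(RECORD_COLUMNS, cols))
    dna = []
    if row["dna_binding"] not in ("", "-"):
        for entry in row["dna_binding"].split(";"):
            assay, variant, flags, ref = entry.split("/", 3)
            dna.append(AssayEvidence(
                assay=assay, reference=ref,
                variant=variant if variant != "-" else "not_applicable",
                verification=_parse_flags(flags),
            ))
    tf = []
    if row["tf_binding"] not in ("", "-"):
        for entry in row["tf_binding"].split(";"):
            assay, partner, ref = entry.split("/", 2)
            tf.append((AssayEvidence(assay=assay, reference=ref), partner if partner != "-" else None))
    regulation = []
    if row["regulation"] not in ("", "-"):
        for entry in row["regulation"].split(";"):
            assay, identification, readout, direction, ref = entry.split("/", 4)
            regulation.append((AssayEvidence(assay=assay, reference=ref), identification, readout, direction))
    return CurationRecord(
        gene_product=(row["db"], row["object_id"], row["symbol"]),
        taxon=row["taxon"],
        paper_refs=tuple(r for r in row["refs"].split("|") if r),
        binding_granularity=row["granularity"],
        dna_binding_evidence=tuple(dna),
        tf_binding_evidence=tuple(tf),
        regulation_evidence=tuple(regulation),
        contributes_to=row["contributes_to"] == "1",
        binding_corroboration=row["binding_corroboration"] == "1",
        target_genes=tuple(g for g in row["target_genes"].split("|") if g),
    )


def read_records(source: TextIO) -> list[CurationRecord]:
    """Read curation records from the package's TSV exchange format."""
    records = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if cols == RECORD_COLUMNS:
            continue  # header row
        if len(cols) != len(RECORD_COLUMNS):
            raise RecordError(
                f"line {lineno}: expected {len(RECORD_COLUMNS)} columns, got {len(cols)}"
            )
        try:
            records.append(_record_from_row(cols, lineno))
        except (ValueError, RecordError) as exc:
            raise RecordError(f"line {lineno}: {exc}") from exc
    return records


def write_records(records: Iterable[CurationRecord], sink: TextIO) -> None:
    """Write curation records in the TSV exchange format (with header)."""
    sink.write("\t".join(RECORD_COLUMNS) + "\n")
    for record in records:
        db, object_id, symbol = record.gene_product
        dna = ";".join(
            "/".join([
                ev.assay,
                ev.variant if ev.variant != "not_applicable" else "-",
                "+".join(sorted(ev.verification)) or "-",
                ev.reference,
            ])
            for ev in record.dna_binding_evidence
        )
        tf = ";".join(
            "/".join([ev.assay, partner or "-", ev.reference])
            for ev, partner in record.tf_binding_evidence
        )
        regulation = ";".join(
            "/".join([ev.assay, identification, readout, direction, ev.reference])
            for ev, identification, readout, direction in record.regulation_evidence
        )
        sink.write("\t".join([
            db, object_id, symbol, record.taxon,
            "|".join(record.paper_refs), record.binding_granularity,
            "1" if record.contributes_to else "0",
            "1" if record.binding_corroboration else "0",
            "|".join(record.target_genes),
            dna or "-", tf or "-", regulation or "-",
        ]) + "\n")
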
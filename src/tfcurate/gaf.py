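"""GAF 2.0 reading, writing and record-level validation.

One :class:`Annotation` is one 17-column GAF 2.0 data line.  Reading and
writing are lossless on every field the curation engine produces, including
``contributes_to``/``NOT`` qualifiers, pipe-separated with/from values and
``has_regulation_target(...)`` annotation extensions.

Validation enforces the evidence-code bookkeeping that DbTF curation relies
on: an IC (inferred-by-curator) record must cite GO_REF:0000036 and carry
the two contributing GO IDs in with/from, and an IPI record must name its
interaction partner.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, TextIO

if TYPE_CHECKING:  # pragma: no cover
    from .ontology import OntologyGraph

logger = logging.getLogger("tfcurate.gaf")

GAF_VERSION_HEADER = "!gaf-version: 2.0"
GAF_COLUMNS = 17

EVIDENCE_CODES = frozenset({"IDA", "IMP", "IPI", "IC"})
ASPECTS = frozenset({"F", "P", "C"})
QUALIFIERS = frozenset({"contributes_to", "NOT"})
GO_REF_IC = "GO_REF:0000036"

NAMESPACE_TO_ASPECT = {
    "molecular_function": "F",
    "biological_process": "P",
    "cellular_component": "C",
}

_GO_ID = re.compile(r"^GO:\d{7}$")
_EXTENSION = re.compile(r"^([A-Za-z_]+)\((.+)\)$")


class GafError(Exception):
    """Base class for GAF I/O failures."""


class GafFormatError(GafError):
    """Structurally invalid GAF input; message names the line."""


class GafValidationError(GafError):
    """An annotation violates a record invariant; message names record and rule."""


@dataclass(frozen=True)
class Annotation:
    """One GAF 2.0 record (gene product x GO term x evidence x provenance)."""

    db: str
    object_id: str
    symbol: str
    go_id: str
    references: tuple[str, ...]
    evidence_code: str
    aspect: str
    taxon: str
    date: str
    assigned_by: str
    qualifiers: tuple[str, ...] = ()
    with_from: tuple[str, ...] = ()
    object_name: str = ""
    synonyms: tuple[str, ...] = ()
    object_type: str = "protein"
    extensions: tuple[tuple[str, str], ...] = ()
    form_id: str = ""


def validate_annotation(ann: Annotation, graph: "OntologyGraph | None" = None) -> list[str]:
    """Return the list of invariant violations for one annotation (empty if valid)."""
    problems: list[str] = []
    if ann.evidence_code not in EVIDENCE_CODES:
        problems.append(f"evidence code {ann.evidence_code!r} outside supported set {sorted(EVIDENCE_CODES)}")
    if ann.aspect not in ASPECTS:
        problems.append(f"aspect {ann.aspect!r} not one of F/P/C")
    if not ann.references:
        problems.append("references must be non-empty")
    if not _GO_ID.match(ann.go_id):
        problems.append(f"GO id {ann.go_id!r} malformed")
    for q in ann.qualifiers:
        if q not in QUALIFIERS:
            problems.append(f"unsupported qualifier {q!r}")
    if ann.evidence_code == "IC":
        if not ann.with_from:
            problems.append("IC requires non-empty with/from")
        elif not all(_GO_ID.match(x) for x in ann.with_from):
            problems.append("IC with/from entries must all be GO accessions")
        if GO_REF_IC not in ann.references:
            problems.append(f"IC requires reference {GO_REF_IC}")
    if ann.evidence_code == "IPI" and not ann.with_from:
        problems.append("IPI requires non-empty with/from (interaction partner)")
    if "contributes_to" in ann.qualifiers and ann.aspect != "F":
        problems.append("contributes_to qualifier only valid on aspect F")
    if graph is not None and ann.go_id in graph:
        expected = NAMESPACE_TO_ASPECT[graph.namespace_of(ann.go_id)]
        if ann.aspect != expected:
            problems.append(
                f"aspect {ann.aspect} disagrees with namespace of {ann.go_id} (expected {expected})"
            )
    return problems


def _split(value: str) -> tuple[str, ...]:
    return tuple(v for v in value.split("|") if v) if value else ()


def _parse_extensions(value: str, lineno: int) -> tuple[tuple[str, str], ...]:
    if not value:
        return ()
    out = []
    for part in value.split(","):
        m = _EXTENSION.match(part.strip())
        if not m:
            raise GafFormatError(f"line {lineno}: malformed annotation extension {part!r}")
        out.append((m.group(1), m.group(2)))
    return tuple(out)


def read_gaf(source: TextIO) -> list[Annotation]:
    """Parse a GAF 2.0 stream into annotations, preserving record order."""
    annotations: list[Annotation] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) != GAF_COLUMNS:
            raise GafFormatError(
                f"line {lineno}: expected {GAF_COLUMNS} tab-separated columns, got {len(cols)}"
            )
        evidence = cols[6]
        if evidence not in EVIDENCE_CODES:
            logger.warning(
                "line %d: evidence code %r outside DbTF curation scope; record retained",
                lineno,
                evidence,
            )
        annotations.append(
            Annotation(
                db=cols[0],
                object_id=cols[1],
                symbol=cols[2],
                qualifiers=_split(cols[3]),
                go_id=cols[4],
                references=_split(cols[5]),
                evidence_code=evidence,
                with_from=_split(cols[7]),
                aspect=cols[8],
                object_name=cols[9],
                synonyms=_split(cols[10]),
                object_type=cols[11],
                taxon=cols[12],
                date=cols[13],
                assigned_by=cols[14],
                extensions=_parse_extensions(cols[15], lineno),
                form_id=cols[16],
            )
        )
    return annotations


def format_annotation(ann: Annotation) -> str:
    """Render one annotation as a 17-column GAF 2.0 line."""
    ext = ",".join(f"{rel}({target})" for rel, target in ann.extensions)
    cols = [
        ann.db,
        ann.object_id,
        ann.symbol,
        "|".join(ann.qualifiers),
        ann.go_id,
        "|".join(ann.references),
        ann.evidence_code,
        "|".join(ann.with_from),
        ann.aspect,
        ann.object_name,
        "|".join(ann.synonyms),
        ann.object_type,
        ann.taxon,
        ann.date,
        ann.assigned_by,
        ext,
        ann.form_id,
    ]
    return "\t".join(cols)


def write_gaf(
    annotations: Iterable[Annotation],
    sink: TextIO,
    graph: "OntologyGraph | None" = None,
    validate: bool = True,
) -> None:
    """Write annotations as GAF 2.0; validates record invariants at write time."""
    sink.write(GAF_VERSION_HEADER + "\n")
    for index, ann in enumerate(annotations):
        if validate:
            problems = validate_annotation(ann, graph)
            if problems:
                raise GafValidationError(f"record {index}: {problems[0]}")
        sink.write(format_annotation(ann) + "\n")
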
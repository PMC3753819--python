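"""GO subgraph container and OBO flat-file import.

Holds the small Gene Ontology subgraph needed for DbTF (sequence-specific
DNA-binding transcription factor) curation: sequence-specific DNA-binding
molecular-function terms, transcription-regulation biological-process terms
and the composite "transcription factor activity" terms that tie the two
together through ``has_part`` and ``part_of`` relations.  The graph answers
the reachability queries the inference engine needs (ancestors, is_a
specificity, inherited relation targets).

A hand-encoded fixture subgraph ships with the package (see
:mod:`tfcurate.fixtures`), so importing a full GO release is optional
enrichment, not a requirement.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO

import networkx as nx

logger = logging.getLogger("tfcurate.ontology")

NAMESPACES = frozenset({"molecular_function", "biological_process", "cellular_component"})
REL_TYPES = frozenset({"is_a", "part_of", "has_part"})

_GO_ID = re.compile(r"^GO:\d{7}$")


class OntologyError(Exception):
    """Base class for ontology-layer failures."""


class OboParseError(OntologyError):
    """Malformed OBO input; the message names the offending line."""


class MissingTermError(OntologyError):
    """A requested term id is absent from the source."""

    def __init__(self, missing: Iterable[str]):
        self.missing = sorted(missing)
        super().__init__(f"term id(s) not found in OBO source: {', '.join(self.missing)}")


class ObsoleteTermError(OntologyError):
    """A requested term is obsolete; suggests a replacement when one is recorded."""

    def __init__(self, term_id: str, replacement: str | None):
        self.term_id = term_id
        self.replacement = replacement
        hint = f"; consider {replacement}" if replacement else ""
        super().__init__(f"term {term_id} is obsolete{hint}")


class UnknownTermError(OntologyError, KeyError):
    """A term id not present in the graph."""

    def __init__(self, term_id: str):
        self.term_id = term_id
        super().__init__(f"unknown term: {term_id}")


@dataclass(frozen=True)
class OntologyTerm:
    """A single GO term: accession, label and GO aspect (namespace)."""

    term_id: str
    name: str
    namespace: str

    def __post_init__(self) -> None:
        if not _GO_ID.match(self.term_id):
            raise ValueError(f"term_id must match GO:\\d{{7}}, got {self.term_id!r}")
        if self.namespace not in NAMESPACES:
            raise ValueError(f"namespace must be one of {sorted(NAMESPACES)}, got {self.namespace!r}")


@dataclass(frozen=True)
class Relation:
    """A typed directed edge subject --rel_type--> object between two terms."""

    subject: str
    rel_type: str
    object: str

    def __post_init__(self) -> None:
        if self.subject == self.object:
            raise ValueError(f"self-relation not allowed: {self.subject} {self.rel_type} {self.object}")
        if self.rel_type not in REL_TYPES:
            raise ValueError(f"rel_type must be one of {sorted(REL_TYPES)}, got {self.rel_type!r}")


class OntologyGraph:
    """Typed multigraph over :class:`OntologyTerm` with is_a/part_of/has_part edges.

    The is_a restriction must stay acyclic; :meth:`validate` checks this.
    """

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()
        self._terms: dict[str, OntologyTerm] = {}

    # -- construction -----------------------------------------------------

    def add_term(self, term: OntologyTerm) -> None:
        self._terms[term.term_id] = term
        self._g.add_node(term.term_id)

    def add_relation(self, relation: Relation) -> None:
        for end in (relation.subject, relation.object):
            if end not in self._terms:
                raise UnknownTermError(end)
        self._g.add_edge(relation.subject, relation.object, key=relation.rel_type)

    # -- inspection -------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __iter__(self) -> Iterator[str]:
        return iter(self._terms)

    def __len__(self) -> int:
        return len(self._terms)

    def term(self, term_id: str) -> OntologyTerm:
        try:
            return self._terms[term_id]
        except KeyError:
            raise UnknownTermError(term_id) from None

    def namespace_of(self, term_id: str) -> str:
        return self.term(term_id).namespace

    @property
    def terms(self) -> dict[str, OntologyTerm]:
        return dict(self._terms)

    @property
    def relations(self) -> frozenset[Relation]:
        return frozenset(
            Relation(u, key, v) for u, v, key in self._g.edges(keys=True)
        )

    # -- queries ----------------------------------------------------------

    def ancestors(self, term_id: str, rel_types: Iterable[str]) -> set[str]:
        """Transitive closure of ``term_id`` over ``rel_types``, excluding itself."""
        if term_id not in self._terms:
            raise UnknownTermError(term_id)
        wanted = frozenset(rel_types)
        seen: set[str] = set()
        stack = [term_id]
        while stack:
            current = stack.pop()
            for _, obj, key in self._g.out_edges(current, keys=True):
                if key in wanted and obj not in seen:
                    seen.add(obj)
                    stack.append(obj)
        seen.discard(term_id)
        return seen

    def is_more_specific(self, a: str, b: str) -> bool:
        """True iff ``a`` is a strict is_a descendant of ``b``.

        Specificity is is_a-only: part_of/has_part connect GO aspects,
        they do not rank granularity.
        """
        if a not in self._terms:
            raise UnknownTermError(a)
        if b not in self._terms:
            raise UnknownTermError(b)
        if a == b:
            return False
        return b in self.ancestors(a, {"is_a"})

    def direct_targets(self, term_id: str, rel_type: str) -> set[str]:
        if term_id not in self._terms:
            raise UnknownTermError(term_id)
        return {obj for _, obj, key in self._g.out_edges(term_id, keys=True) if key == rel_type}

    def effective_targets(self, term_id: str, rel_type: str) -> set[str]:
        """Relation targets of a term plus those inherited from its is_a ancestors.

        GO relations propagate down the is_a hierarchy: a child of a term
        with ``has_part X`` also has part X.
        """
        out = self.direct_targets(term_id, rel_type)
        for anc in self.ancestors(term_id, {"is_a"}):
            out |= self.direct_targets(anc, rel_type)
        return out

    def validate(self) -> None:
        """Raise :class:`OntologyError` if a structural invariant is broken."""
        isa = nx.DiGraph(
            (u, v) for u, v, key in self._g.edges(keys=True) if key == "is_a"
        )
        if not nx.is_directed_acyclic_graph(isa):
            cycle = nx.find_cycle(isa)
            raise OntologyError(f"is_a cycle detected: {cycle}")


# -- OBO flat-file import/export ------------------------------------------
#
# The reader is deliberately strict: it reports the line number of a
# malformed stanza line, resolves alt_ids to primary ids, rejects obsolete
# requested terms (suggesting replaced_by/consider when present) and warns
# on relationship types outside is_a/part_of/has_part.


def _strip_obo_comment(value: str) -> str:
    # trailing " ! label" comments
    pos = value.find(" !")
    return (value[:pos] if pos >= 0 else value).strip()


def _parse_obo_stanzas(source: TextIO):
    """Yield (kind, fields, first_line_no) per stanza plus the header dict."""
    header: dict[str, str] = {}
    stanzas: list[tuple[str, dict[str, list[str]], int]] = []
    kind: str | None = None
    fields: dict[str, list[str]] = {}
    start = 0
    in_header = True
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if not stripped or stripped.startswith("!"):
            continue
        if stripped.startswith("[") and stripped.endswith("]"):
            if kind is not None:
                stanzas.append((kind, fields, start))
            kind = stripped[1:-1]
            fields = {}
            start = lineno
            in_header = False
            continue
        if ":" not in stripped:
            where = "header" if in_header else f"[{kind}] stanza"
            raise OboParseError(f"line {lineno}: malformed {where} line (no tag): {stripped!r}")
        tag, _, value = stripped.partition(":")
        tag = tag.strip()
        value = _strip_obo_comment(value)
        if in_header:
            header[tag] = value
        else:
            fields.setdefault(tag, []).append(value)
    if kind is not None:
        stanzas.append((kind, fields, start))
    return header, stanzas


def load_obo_subset(obo_source: TextIO, keep_ids: Iterable[str]) -> OntologyGraph:
    """Load the induced subgraph of an OBO file reachable from ``keep_ids``.

    Starting from ``keep_ids`` (after alt_id resolution), all terms reachable
    via is_a/part_of/has_part are pulled in.  Obsolete terms are excluded;
    requesting one raises :class:`ObsoleteTermError` with a replacement
    suggestion when the file records one.  Relationship lines of types other
    than part_of/has_part are ignored with a warning.
    """
    keep = set(keep_ids)
    if not keep:
        raise ValueError("keep_ids must be non-empty")

    header, stanzas = _parse_obo_stanzas(obo_source)
    default_ns = header.get("default-namespace")

    records: dict[str, dict] = {}
    alt_to_primary: dict[str, str] = {}
    for kind, fields, lineno in stanzas:
        if kind != "Term":
            continue
        ids = fields.get("id", [])
        if len(ids) != 1:
            raise OboParseError(f"line {lineno}: [Term] stanza must carry exactly one id")
        term_id = ids[0]
        names = fields.get("name", [""])
        namespace = fields.get("namespace", [default_ns] if default_ns else [])
        if not namespace or namespace[0] is None:
            raise OboParseError(
                f"line {lineno}: term {term_id} has no namespace and the file sets no default-namespace"
            )
        obsolete = fields.get("is_obsolete", ["false"])[0].lower() == "true"
        replacement = (fields.get("replaced_by") or fields.get("consider") or [None])[0]
        relations: list[tuple[str, str]] = [("is_a", v) for v in fields.get("is_a", [])]
        for rel_line in fields.get("relationship", []):
            parts = rel_line.split(None, 1)
            if len(parts) != 2:
                raise OboParseError(f"line {lineno}: malformed relationship line {rel_line!r}")
            rel_type, target = parts[0], parts[1].strip()
            if rel_type not in ("part_of", "has_part"):
                logger.warning("ignoring relationship of unrecognized type %r on %s", rel_type, term_id)
                continue
            relations.append((rel_type, target))
        records[term_id] = {
            "name": names[0],
            "namespace": namespace[0],
            "obsolete": obsolete,
            "replacement": replacement,
            "relations": relations,
        }
        for alt in fields.get("alt_id", []):
            alt_to_primary[alt] = term_id

    def resolve(term_id: str) -> str:
        return term_id if term_id in records else alt_to_primary.get(term_id, term_id)

    resolved_keep = {resolve(t) for t in keep}
    missing = {t for t in resolved_keep if t not in records}
    if missing:
        raise MissingTermError(missing)
    for t in resolved_keep:
        if records[t]["obsolete"]:
            raise ObsoleteTermError(t, records[t]["replacement"])

    # reachability closure over the three relation types
    selected: set[str] = set()
    stack = list(resolved_keep)
    while stack:
        current = stack.pop()
        if current in selected:
            continue
        selected.add(current)
        for _, target in records[current]["relations"]:
            target = resolve(target)
            if target not in records:
                logger.warning("dangling relation target %s from %s; skipped", target, current)
                continue
            if records[target]["obsolete"]:
                logger.warning("relation target %s is obsolete; skipped", target)
                continue
            if target not in selected:
                stack.append(target)

    graph = OntologyGraph()
    for term_id in selected:
        rec = records[term_id]
        graph.add_term(OntologyTerm(term_id, rec["name"], rec["namespace"]))
    for term_id in selected:
        for rel_type, target in records[term_id]["relations"]:
            target = resolve(target)
            if target in selected:
                graph.add_relation(Relation(term_id, rel_type, target))
    graph.validate()
    return graph


def write_obo(graph: OntologyGraph, sink: TextIO) -> None:
    """Serialize a graph to OBO 1.2 text; inverse of :func:`load_obo_subset`."""
    sink.write("format-version: 1.2\n")
    for term_id in sorted(graph.terms):
        term = graph.term(term_id)
        sink.write(f"\n[Term]\nid: {term.term_id}\nname: {term.name}\nnamespace: {term.namespace}\n")
        for obj in sorted(graph.direct_targets(term_id, "is_a")):
            sink.write(f"is_a: {obj} ! {graph.term(obj).name}\n")
        for rel_type in ("part_of", "has_part"):
            for obj in sorted(graph.direct_targets(term_id, rel_type)):
                sink.write(f"relationship: {rel_type} {obj} ! {graph.term(obj).name}\n")
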
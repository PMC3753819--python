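"""Shared fixtures: the bundled ontology subgraph and a brute-force oracle.

The oracle re-derives composite-activity inference from the raw relation
tuples with plain set arithmetic — no calls into the inference engine — so
agreement between the two is a meaningful check.
"""

from __future__ import annotations

import pytest

from tfcurate import figure1_subgraph
from tfcurate.ontology import OntologyGraph


@pytest.fixture(scope="session")
def subgraph_fixture():
    return figure1_subgraph()


@pytest.fixture(scope="session")
def graph(subgraph_fixture) -> OntologyGraph:
    return subgraph_fixture.combined()


def brute_force_composites(graph: OntologyGraph, binding_go: str, regulation_go: str) -> list[str]:
    """Enumerate every candidate activity term and check its constraints.

    A molecular-function term with has_part and part_of requirements (its
    own plus those inherited down is_a) is a composite candidate; it matches
    when every has_part target sits at or above the binding evidence term
    and every part_of target at or above the regulation evidence term.
    Returns the is_a-most-specific matches, sorted.
    """
    isa: dict[str, set[str]] = {}
    has_part: dict[str, set[str]] = {}
    part_of: dict[str, set[str]] = {}
    for rel in graph.relations:
        bucket = {"is_a": isa, "has_part": has_part, "part_of": part_of}[rel.rel_type]
        bucket.setdefault(rel.subject, set()).add(rel.object)

    def isa_closure(term: str) -> set[str]:
        seen = {term}
        stack = [term]
        while stack:
            for parent in isa.get(stack.pop(), ()):
                if parent not in seen:
                    seen.add(parent)
                    stack.append(parent)
        return seen

    binding_up = isa_closure(binding_go)
    regulation_up = isa_closure(regulation_go)
    matches = []
    for term_id, term in graph.terms.items():
        if term.namespace != "molecular_function":
            continue
        lineage = isa_closure(term_id)
        required_parts = set().union(*(has_part.get(a, set()) for a in lineage))
        required_processes = set().union(*(part_of.get(a, set()) for a in lineage))
        if not required_parts or not required_processes:
            continue
        if required_parts <= binding_up and required_processes <= regulation_up:
            matches.append(term_id)
    most_specific = [
        t for t in matches
        if not any(o != t and t in isa_closure(o) for o in matches)
    ]
    return sorted(most_specific)
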
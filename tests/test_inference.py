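"""Composite-term inference: printed anchors, oracle equivalence, propagation."""

import itertools

import pytest

from conftest import brute_force_composites
from tfcurate.evidence import AssayEvidence
from tfcurate.gaf import GO_REF_IC
from tfcurate.inference import (
    DIRECTION_TERMS,
    GRANULARITY_TERMS,
    BindingClass,
    InferenceRefusedError,
    RegulationClass,
    RuleViolationError,
    build_annotations,
    infer_composite_term,
    propagate_evidence,
)
from tfcurate.workflow import CurationRecord

DNA_GRANULARITIES = ["sequence_specific", "regulatory_region", "rnapii_regulatory", "proximal", "distal"]
DIRECTIONS = ["unspecified", "positive", "negative", "both"]

ANCHORS = [
    # (mode, granularity, direction, expected composite term(s))
    ("dna", "rnapii_regulatory", "unspecified", ("GO:0000981",)),
    ("dna", "proximal", "positive", ("GO:0001077",)),
    ("dna", "distal", "positive", ("GO:0001205",)),
    ("tf_binding", "tf_generic", "unspecified", ("GO:0001076",)),
    ("dna", "proximal", "both", ("GO:0001077", "GO:0001078")),
]


class TestInferCompositeTerm:
    @pytest.mark.parametrize("mode,granularity,direction,expected", ANCHORS)
    def test_printed_anchors(self, graph, mode, granularity, direction, expected):
        result = infer_composite_term(
            BindingClass(mode=mode, granularity=granularity),
            RegulationClass(direction=direction),
            graph,
        )
        assert result == expected

    def test_agrees_with_brute_force_oracle_everywhere(self, graph):
        """Constraint search matches independent enumeration on all inputs."""
        combos = [
            (mode, granularity)
            for mode in ("dna", "dna_contributes")
            for granularity in DNA_GRANULARITIES
        ] + [("tf_binding", "tf_generic")]
        checked = 0
        for (mode, granularity), direction in itertools.product(combos, DIRECTIONS):
            result = infer_composite_term(
                BindingClass(mode=mode, granularity=granularity),
                RegulationClass(direction=direction),
                graph,
            )
            expected = []
            for regulation_go in DIRECTION_TERMS[direction]:
                for term in brute_force_composites(graph, GRANULARITY_TERMS[granularity], regulation_go):
                    if term not in expected:
                        expected.append(term)
            assert sorted(result) == sorted(expected), (mode, granularity, direction)
            assert len(result) == len(expected)  # no duplicate or tied terms
            checked += 1
        assert checked == 44  # 2 dna modes x 5 granularities x 4 directions + tf x 4

    def test_refining_granularity_never_generalizes_the_composite(self, graph):
        ladder = ["sequence_specific", "regulatory_region", "rnapii_regulatory", "proximal"]
        for direction in ("unspecified", "positive", "negative"):
            previous = None
            for granularity in ladder:
                [term] = infer_composite_term(
                    BindingClass(mode="dna", granularity=granularity),
                    RegulationClass(direction=direction),
                    graph,
                )
                if previous is not None:
                    # never moves to a strict is_a ancestor of the previous result
                    assert not graph.is_more_specific(previous, term)
                previous = term

    def test_mode_granularity_mismatch_refused(self):
        with pytest.raises(InferenceRefusedError):
            BindingClass(mode="tf_binding", granularity="proximal")
        with pytest.raises(InferenceRefusedError):
            BindingClass(mode="dna", granularity="tf_generic")


PROPAGATION_TABLE = [
    # (binding code, regulation code, same paper) -> composite records
    ("IDA", "IDA", True, [("IDA", "none")]),
    ("IMP", "IMP", True, [("IMP", "none")]),
    ("IDA", "IMP", True, [("IDA", "none"), ("IMP", "none")]),
    ("IMP", "IDA", True, [("IMP", "none"), ("IDA", "none")]),
    ("IPI", "IDA", True, [("IPI", "partner"), ("IDA", "none")]),
    ("IDA", "IDA", False, [("IC", "go_ids")]),
    ("IMP", "IMP", False, [("IC", "go_ids")]),
    ("IDA", "IMP", False, [("IC", "go_ids")]),
    ("IMP", "IDA", False, [("IC", "go_ids")]),
    ("IPI", "IDA", False, [("IC", "go_ids")]),
]


class TestPropagateEvidence:
    @pytest.mark.parametrize("binding,regulation,same_ref,expected", PROPAGATION_TABLE)
    def test_golden_table(self, binding, regulation, same_ref, expected):
        mode = "tf_binding" if binding == "IPI" else "dna"
        assert propagate_evidence(binding, regulation, same_ref, binding_mode=mode) == expected

    def test_ipi_with_dna_binding_mode_forbidden(self):
        with pytest.raises(RuleViolationError, match="TF binding"):
            propagate_evidence("IPI", "IDA", True, binding_mode="dna")

    def test_regulation_side_never_ipi(self):
        with pytest.raises(RuleViolationError):
            propagate_evidence("IDA", "IPI", True)


def proximal_record(regulation_ref="PMID:1", **overrides):
    base = dict(
        gene_product=("FAKEDB", "SYNTF00001", "syntf1"),
        taxon="taxon:9606",
        paper_refs=tuple(sorted({"PMID:1", regulation_ref})),
        binding_granularity="proximal",
        dna_binding_evidence=(
            AssayEvidence(assay="emsa", variant="purified", reference="PMID:1"),
        ),
        regulation_evidence=(
            (AssayEvidence(assay="reporter_gene", reference=regulation_ref),
             "ectopic_wt", "reporter_wt_tfbs", "positive"),
        ),
        target_genes=("FAKEGENE:G1",),
    )
    base.update(overrides)
    return CurationRecord(**base)


class TestBuildAnnotations:
    def test_same_paper_record_yields_binding_regulation_and_composite(self, graph):
        annotations = build_annotations(proximal_record(), graph)
        assert [(a.go_id, a.evidence_code) for a in annotations] == [
            ("GO:0000978", "IDA"),
            ("GO:0045944", "IDA"),
            ("GO:0001077", "IDA"),
        ]
        regulation = annotations[1]
        assert regulation.extensions == (("has_regulation_target", "FAKEGENE:G1"),)
        assert regulation.aspect == "P"

    def test_cross_paper_record_yields_curator_inference(self, graph):
        annotations = build_annotations(proximal_record(regulation_ref="PMID:2"), graph)
        composite = annotations[-1]
        assert composite.go_id == "GO:0001077"
        assert composite.evidence_code == "IC"
        assert composite.references == (GO_REF_IC,)
        assert composite.with_from == ("GO:0000978", "GO:0045944")

    def test_binding_only_record_emits_no_composite(self, graph):
        record = proximal_record(regulation_evidence=())
        annotations = build_annotations(record, graph)
        assert [a.go_id for a in annotations] == ["GO:0000978"]

    def test_dismissed_binding_emits_no_composite(self, graph):
        record = proximal_record(dna_binding_evidence=(
            AssayEvidence(assay="emsa", variant="native_extract", reference="PMID:1"),
        ))
        annotations = build_annotations(record, graph)
        assert [a.go_id for a in annotations] == ["GO:0045944"]

    def test_contributes_to_propagates_to_binding_and_composite(self, graph):
        annotations = build_annotations(proximal_record(contributes_to=True), graph)
        binding, regulation, composite = annotations
        assert binding.qualifiers == ("contributes_to",)
        assert regulation.qualifiers == ()  # BP annotation never carries it
        assert composite.qualifiers == ("contributes_to",)

    def test_mixed_codes_same_paper_yield_two_composite_records(self, graph):
        record = proximal_record(dna_binding_evidence=(
            AssayEvidence(assay="emsa", variant="mutant_extract", reference="PMID:1"),
        ))
        annotations = build_annotations(record, graph)
        composites = [a for a in annotations if a.go_id == "GO:0001077"]
        assert [a.evidence_code for a in composites] == ["IMP", "IDA"]

    def test_dna_and_tf_binding_yield_both_composite_families(self, graph):
        record = proximal_record(tf_binding_evidence=(
            (AssayEvidence(assay="two_hybrid", reference="PMID:1"), "FAKEDB:P1"),
        ))
        annotations = build_annotations(record, graph)
        go_ids = {a.go_id for a in annotations}
        assert {"GO:0001077", "GO:0001190"} <= go_ids
        ipi = [a for a in annotations if a.evidence_code == "IPI"]
        assert all(a.with_from == ("FAKEDB:P1",) for a in ipi)
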
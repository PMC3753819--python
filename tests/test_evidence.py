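"""Assay-evidence classification against the published rule tables."""

import io
import itertools

import pytest

from tfcurate.evidence import (
    DEFAULT_REGULATION_MATRIX,
    AssayEvidence,
    ConfigurationError,
    EvidenceVerdict,
    WrongCategoryError,
    classify_dna_binding,
    classify_regulation,
    classify_tf_binding,
    load_regulation_matrix,
)

# Golden rule table for specific-DNA-binding assays:
# (assay, variant, flags) -> (evidence code or None, PSI-MI code or None)
DNA_BINDING_TABLE = [
    ("emsa", "native_extract", frozenset(), None, "MI:0413"),
    ("emsa", "ectopic_extract", frozenset(), "IDA", "MI:0413"),
    ("emsa", "purified", frozenset(), "IDA", "MI:0413"),
    ("emsa", "mutant_extract", frozenset(), "IMP", "MI:0413"),
    ("emsa", "purified_mutant", frozenset(), "IMP", "MI:0413"),
    ("emsa_supershift", "native_extract", frozenset(), "IDA", "MI:0412"),
    ("emsa_supershift", "ectopic_extract", frozenset(), "IDA", "MI:0412"),
    ("emsa_supershift", "purified", frozenset(), "IDA", "MI:0412"),
    ("emsa_supershift", "mutant_extract", frozenset(), "IMP", "MI:0412"),
    ("emsa_supershift", "purified_mutant", frozenset(), "IMP", "MI:0412"),
    ("footprinting", "not_applicable", frozenset(), "IDA", "MI:0417"),
    ("dnase_footprint", "not_applicable", frozenset(), "IDA", "MI:0606"),
    ("methylation_interference", "not_applicable", frozenset(), "IDA", "MI:1189"),
    ("uv_footprint", "not_applicable", frozenset(), "IDA", "MI:1191"),
    ("dms_footprint", "not_applicable", frozenset(), "IDA", "MI:0603"),
    ("hydroxy_footprint", "not_applicable", frozenset(), "IDA", "MI:1190"),
    ("kmno4_footprint", "not_applicable", frozenset(), "IDA", "MI:0604"),
    ("affinity_chromatography", "not_applicable", frozenset(), "IDA", "MI:0004"),
    ("pull_down", "not_applicable", frozenset(), "IDA", "MI:0096"),
    ("southwestern_blot", "not_applicable", frozenset(), "IDA", None),
    ("selex", "not_applicable", frozenset(), "IDA", "MI:0657"),
    ("xray_crystallography", "not_applicable", frozenset({"dna_cocrystal"}), "IDA", "MI:0114"),
]

# Golden rule table for TF-binding (protein-protein) assays:
# (assay, partner available) -> (code, MI)
TF_BINDING_TABLE = [
    ("two_hybrid", True, "IPI", "MI:0018"),
    ("copurification", True, "IPI", "MI:0004"),
    ("copurification", False, "IDA", "MI:0004"),
    ("coimmunoprecipitation", True, "IPI", "MI:0019"),
    ("coimmunoprecipitation", False, "IDA", "MI:0019"),
]


class TestDnaBinding:
    @pytest.mark.parametrize("assay,variant,flags,code,mi", DNA_BINDING_TABLE)
    def test_golden_table(self, assay, variant, flags, code, mi):
        verdict = classify_dna_binding(
            AssayEvidence(assay=assay, variant=variant, verification=flags, reference="PMID:1")
        )
        assert verdict.category == "dna_binding"
        assert verdict.admissible == (code is not None)
        assert verdict.evidence_code == code
        assert verdict.psimi_code == mi

    def test_unverified_native_extract_reason_cites_dismissal(self):
        verdict = classify_dna_binding(
            AssayEvidence(assay="emsa", variant="native_extract", reference="PMID:1")
        )
        assert not verdict.admissible
        assert "native extract" in verdict.reason

    def test_native_extract_rescued_only_by_both_competition_flags(self):
        for flags in ({"wt_probe_competition"}, {"mutant_probe_competition"}):
            verdict = classify_dna_binding(AssayEvidence(
                assay="emsa", variant="native_extract",
                verification=frozenset(flags), reference="PMID:1",
            ))
            assert not verdict.admissible
        rescued = classify_dna_binding(AssayEvidence(
            assay="emsa", variant="native_extract",
            verification=frozenset({"wt_probe_competition", "mutant_probe_competition"}),
            reference="PMID:1",
        ))
        assert rescued.evidence_code == "IDA"

    def test_xray_without_cocrystal_inadmissible(self):
        verdict = classify_dna_binding(
            AssayEvidence(assay="xray_crystallography", reference="PMID:1")
        )
        assert not verdict.admissible
        assert "co-crystal" in verdict.reason

    def test_wrong_category_rejected(self):
        with pytest.raises(WrongCategoryError):
            classify_dna_binding(AssayEvidence(assay="two_hybrid", reference="PMID:1"))

    def test_never_returns_ipi(self):
        for assay, variant, flags, code, _ in DNA_BINDING_TABLE:
            verdict = classify_dna_binding(
                AssayEvidence(assay=assay, variant=variant, verification=flags, reference="PMID:1")
            )
            assert verdict.evidence_code != "IPI"


class TestTfBinding:
    @pytest.mark.parametrize("assay,with_partner,code,mi", TF_BINDING_TABLE)
    def test_golden_table(self, assay, with_partner, code, mi):
        partner = "FAKEDB:P1" if with_partner else None
        verdict = classify_tf_binding(AssayEvidence(assay=assay, reference="PMID:1"), partner)
        assert verdict.category == "tf_binding"
        assert verdict.evidence_code == code
        assert verdict.psimi_code == mi

    def test_two_hybrid_without_partner_inadmissible(self):
        verdict = classify_tf_binding(AssayEvidence(assay="two_hybrid", reference="PMID:1"), None)
        assert not verdict.admissible

    def test_never_returns_imp(self):
        for assay, with_partner, *_ in TF_BINDING_TABLE:
            partner = "FAKEDB:P1" if with_partner else None
            verdict = classify_tf_binding(AssayEvidence(assay=assay, reference="PMID:1"), partner)
            assert verdict.evidence_code != "IMP"

    def test_wrong_category_rejected(self):
        with pytest.raises(WrongCategoryError):
            classify_tf_binding(AssayEvidence(assay="reporter_gene", reference="PMID:1"))


class TestRegulation:
    def reporter(self):
        return AssayEvidence(assay="reporter_gene", reference="PMID:1")

    def test_ectopic_wildtype_is_direct_assay(self):
        verdict = classify_regulation(self.reporter(), "ectopic_wt", "reporter_wt_tfbs")
        assert verdict.evidence_code == "IDA"

    @pytest.mark.parametrize("identification", ["ectopic_mut", "knock_down", "knock_out"])
    def test_mutant_and_knockdown_are_mutant_phenotype(self, identification):
        verdict = classify_regulation(self.reporter(), identification, "reporter_wt_tfbs")
        assert verdict.evidence_code == "IMP"

    def test_native_identification_alone_inadmissible(self):
        verdict = classify_regulation(self.reporter(), "native", "reporter_wt_tfbs")
        assert not verdict.admissible

    def test_knockout_mrna_readout_needs_binding_corroboration(self):
        mrna = AssayEvidence(assay="tg_mrna_expression", reference="PMID:1")
        blocked = classify_regulation(mrna, "knock_out", "tg_mrna")
        assert not blocked.admissible
        allowed = classify_regulation(mrna, "knock_out", "tg_mrna", binding_corroboration=True)
        assert allowed.evidence_code == "IMP"

    def test_missing_matrix_key_is_configuration_error(self):
        partial = {("ectopic_wt", "reporter_wt_tfbs"): "IDA"}
        with pytest.raises(ConfigurationError, match="knock_down"):
            classify_regulation(self.reporter(), "knock_down", "reporter_wt_tfbs", matrix=partial)

    def test_yaml_matrix_overrides_default(self):
        config = io.StringIO("ectopic_wt:\n  reporter_wt_tfbs: inadmissible\n")
        matrix = load_regulation_matrix(config)
        verdict = classify_regulation(self.reporter(), "ectopic_wt", "reporter_wt_tfbs", matrix=matrix)
        assert not verdict.admissible

    def test_yaml_matrix_rejects_unknown_code(self):
        with pytest.raises(ConfigurationError, match="IEP"):
            load_regulation_matrix(io.StringIO("ectopic_wt:\n  reporter_wt_tfbs: IEP\n"))


class TestVerdictInvariants:
    def test_admissibility_and_code_are_linked(self):
        with pytest.raises(ValueError):
            EvidenceVerdict(admissible=False, category="dna_binding", evidence_code="IDA")
        with pytest.raises(ValueError):
            EvidenceVerdict(admissible=True, category="dna_binding", evidence_code=None)

    def test_variant_only_where_the_table_lists_variants(self):
        with pytest.raises(ValueError):
            AssayEvidence(assay="selex", variant="purified", reference="PMID:1")
        with pytest.raises(ValueError):
            AssayEvidence(assay="emsa", reference="PMID:1")  # variant required
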
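"""Classification of experimental assay evidence for DbTF curation.

Maps one experimental observation (assay + TF-presentation variant +
verification flags) to a verdict: is the evidence admissible, for which
evidence category (specific DNA binding, TF binding, transcription
regulation), under which GO evidence code (IDA/IMP/IPI), and with which
PSI-MI assay identifier.

The rules encode a strict reading of what each assay can prove:

* An EMSA run on nuclear extract from native tissue identifies a band shift
  but not the protein causing it, so it is dismissed unless the TF identity
  is pinned down by two-sided competition (wild-type probe competes the
  shift away, a TFBS-point-mutant probe does not) or by a supershift with a
  TF-specific antibody.
* X-ray crystallography proves DNA binding only when the protein is
  co-crystallized with DNA.
* In-vivo occupancy assays (ChIP) are out of scope entirely: they cannot
  distinguish direct DNA contact from piggy-backing on another factor.
* Knock-out/knock-down experiments read out on endogenous target mRNA do
  not by themselves prove transcription regulation; they are admitted only
  when the record carries corroborating direct-binding evidence.

The transcription-regulation decision matrix (TF identification strategy x
readout -> evidence code) ships with a documented default but is
user-configurable via YAML, since conventions here are lab-specific; the
default is provisional.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, TextIO

import yaml

logger = logging.getLogger("tfcurate.evidence")

# -- vocabularies ----------------------------------------------------------

DNA_BINDING_ASSAYS = frozenset({
    "emsa",
    "emsa_supershift",
    "footprinting",
    "dnase_footprint",
    "methylation_interference",
    "uv_footprint",
    "dms_footprint",
    "hydroxy_footprint",
    "kmno4_footprint",
    "affinity_chromatography",
    "pull_down",
    "southwestern_blot",
    "selex",
    "xray_crystallography",
})
TF_BINDING_ASSAYS = frozenset({"two_hybrid", "copurification", "coimmunoprecipitation"})
REGULATION_ASSAYS = frozenset({"reporter_gene", "tg_mrna_expression"})
ASSAYS = DNA_BINDING_ASSAYS | TF_BINDING_ASSAYS | REGULATION_ASSAYS

#: assays for which a TF-presentation variant is meaningful (gel-shift family)
VARIANT_ASSAYS = frozenset({"emsa", "emsa_supershift"})
VARIANTS = frozenset({
    "native_extract",      # nuclear extract from native tissue or cells
    "ectopic_extract",     # extract from cells ectopically expressing the TF
    "purified",            # in-vitro translated or purified TF
    "mutant_extract",      # ectopic expression of a mutated TF
    "purified_mutant",     # purified mutated TF
    "not_applicable",
})
MUTANT_VARIANTS = frozenset({"mutant_extract", "purified_mutant"})

VERIFICATION_FLAGS = frozenset({
    "mutant_probe_competition",  # mutated-TFBS probe fails to compete the shift
    "wt_probe_competition",      # wild-type probe competes the shift away
    "specific_antibody",
    "dna_cocrystal",
})

TF_IDENTIFICATIONS = frozenset({"ectopic_wt", "ectopic_mut", "knock_down", "knock_out", "native"})
READOUTS = frozenset({"reporter_wt_tfbs", "reporter_mut_tfbs", "tg_mrna"})

#: PSI-MI molecular-interaction identifiers per assay.  Southwestern blot
#: has no PSI-MI term (it is MeSH-indexed) and is deliberately absent.
PSIMI_CODES: Mapping[str, str] = {
    "emsa": "MI:0413",
    "emsa_supershift": "MI:0412",
    "footprinting": "MI:0417",
    "dnase_footprint": "MI:0606",
    "methylation_interference": "MI:1189",
    "uv_footprint": "MI:1191",
    "dms_footprint": "MI:0603",
    "hydroxy_footprint": "MI:1190",
    "kmno4_footprint": "MI:0604",
    "affinity_chromatography": "MI:0004",
    "pull_down": "MI:0096",
    "selex": "MI:0657",
    "xray_crystallography": "MI:0114",
    "two_hybrid": "MI:0018",
    "copurification": "MI:0004",
    "coimmunoprecipitation": "MI:0019",
}

_MI_ID = re.compile(r"^MI:\d{4}$")


class EvidenceError(Exception):
    """Base class for evidence-classification failures."""


class WrongCategoryError(EvidenceError):
    """Assay routed to the wrong classifier."""


class ConfigurationError(EvidenceError):
    """Invalid or incomplete decision-matrix configuration."""


@dataclass(frozen=True)
class AssayEvidence:
    """One experimental observation supporting a curation statement."""

    assay: str
    reference: str
    variant: str = "not_applicable"
    verification: frozenset[str] = frozenset()
    psimi_code: str | None = None

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.assay in VARIANT_ASSAYS and self.variant == "not_applicable":
            raise ValueError(f"{self.assay} requires a TF-presentation variant")
        if self.assay not in VARIANT_ASSAYS and self.variant != "not_applicable":
            raise ValueError(f"{self.assay} does not take a TF-presentation variant")
        object.__setattr__(self, "verification", frozenset(self.verification))
        unknown = self.verification - VERIFICATION_FLAGS
        if unknown:
            raise ValueError(f"unknown verification flag(s): {sorted(unknown)}")
        if self.psimi_code is not None and not _MI_ID.match(self.psimi_code):
            raise ValueError(f"psimi_code must match MI:\\d{{4}}, got {self.psimi_code!r}")

    @property
    def mi_code(self) -> str | None:
        """Explicit PSI-MI code if given, else the standard code for the assay."""
        return self.psimi_code or PSIMI_CODES.get(self.assay)


@dataclass(frozen=True)
class EvidenceVerdict:
    """Outcome of classifying one piece of evidence."""

    admissible: bool
    category: str  # dna_binding | tf_binding | transcription_regulation
    evidence_code: str | None = None
    reason: str = ""
    psimi_code: str | None = None

    def __post_init__(self) -> None:
        if not self.admissible and self.evidence_code is not None:
            raise ValueError("inadmissible verdict must not carry an evidence code")
        if self.admissible and self.evidence_code is None:
            raise ValueError("admissible verdict must carry an evidence code")


# -- specific DNA binding --------------------------------------------------

_NATIVE_RESCUE = frozenset({"mutant_probe_competition", "wt_probe_competition"})


def classify_dna_binding(assay: AssayEvidence) -> EvidenceVerdict:
    """Verdict for a specific-DNA-binding assay.

    Gel shifts on unverified native extracts are dismissed; ectopic or
    purified TF presentations give IDA; mutated-TF presentations give IMP
    (the annotation is inferred from the mutant's phenotype).  Supershifts
    identify the TF via antibody, so the native-extract variant is
    admissible.  Crystallography counts only with a protein-DNA co-crystal.
    """
    if assay.assay not in DNA_BINDING_ASSAYS:
        raise WrongCategoryError(f"{assay.assay} is not a specific-DNA-binding assay")
    mi = assay.mi_code

    def ok(code: str, reason: str = "") -> EvidenceVerdict:
        return EvidenceVerdict(True, "dna_binding", code, reason, mi)

    def no(reason: str) -> EvidenceVerdict:
        return EvidenceVerdict(False, "dna_binding", None, reason, mi)

    if assay.assay == "emsa":
        if assay.variant == "native_extract":
            if _NATIVE_RESCUE <= assay.verification:
                return ok("IDA", "native-extract EMSA verified by two-sided probe competition")
            return no(
                "EMSA on unverified native extract: band shift does not identify the TF; "
                "requires wild-type and mutant probe competition or a supershift"
            )
        if assay.variant in MUTANT_VARIANTS:
            return ok("IMP")
        return ok("IDA")
    if assay.assay == "emsa_supershift":
        if assay.variant in MUTANT_VARIANTS:
            return ok("IMP")
        return ok("IDA")
    if assay.assay == "xray_crystallography":
        if "dna_cocrystal" in assay.verification:
            return ok("IDA")
        return no("X-ray structure without a protein-DNA co-crystal does not show DNA binding")
    # footprinting family, affinity chromatography, pull down,
    # southwestern blot, SELEX: direct assays
    return ok("IDA")


# -- TF binding ------------------------------------------------------------

def classify_tf_binding(assay: AssayEvidence, partner_id: str | None = None) -> EvidenceVerdict:
    """Verdict for a protein-protein TF-binding assay.

    Where both IPI and IDA are eligible (co-purification, co-IP), IPI is
    preferred when the interaction partner is identified (it goes into
    with/from); otherwise IDA.  Two-hybrid is IPI-only and therefore needs
    the partner.
    """
    if assay.assay not in TF_BINDING_ASSAYS:
        raise WrongCategoryError(f"{assay.assay} is not a TF-binding assay")
    mi = assay.mi_code
    if assay.assay == "two_hybrid":
        if partner_id is None:
            return EvidenceVerdict(
                False, "tf_binding", None,
                "two-hybrid is IPI-only and IPI requires the interaction partner id", mi,
            )
        return EvidenceVerdict(True, "tf_binding", "IPI", "", mi)
    code = "IPI" if partner_id is not None else "IDA"
    return EvidenceVerdict(True, "tf_binding", code, "", mi)


# -- transcription regulation ----------------------------------------------

#: Default decision matrix (TF identification, readout) -> evidence code or
#: None for inadmissible.  Provisional: override via YAML config.
DEFAULT_REGULATION_MATRIX: Mapping[tuple[str, str], str | None] = {
    (ident, readout): code
    for ident, code in (
        ("ectopic_wt", "IDA"),
        ("ectopic_mut", "IMP"),
        ("knock_down", "IMP"),
        ("knock_out", "IMP"),
        ("native", None),  # native TF identification alone proves nothing
    )
    for readout in sorted(READOUTS)
}

#: combinations admissible only with corroborating direct-binding evidence
_CORROBORATION_REQUIRED = frozenset({
    ("knock_down", "tg_mrna"),
    ("knock_out", "tg_mrna"),
})


def load_regulation_matrix(source: TextIO) -> dict[tuple[str, str], str | None]:
    """Load a YAML decision matrix: ``tf_identification: {readout: code}``.

    Codes are IDA/IMP or the word ``inadmissible``.
    """
    data = yaml.safe_load(source)
    if not isinstance(data, dict):
        raise ConfigurationError("regulation matrix config must be a mapping")
    matrix: dict[tuple[str, str], str | None] = {}
    for ident, row in data.items():
        if ident not in TF_IDENTIFICATIONS:
            raise ConfigurationError(f"unknown TF identification strategy {ident!r}")
        if not isinstance(row, dict):
            raise ConfigurationError(f"matrix row for {ident!r} must map readouts to codes")
        for readout, code in row.items():
            if readout not in READOUTS:
                raise ConfigurationError(f"unknown readout {readout!r}")
            if code == "inadmissible":
                matrix[(ident, readout)] = None
            elif code in ("IDA", "IMP"):
                matrix[(ident, readout)] = code
            else:
                raise ConfigurationError(
                    f"matrix cell ({ident}, {readout}) must be IDA, IMP or inadmissible, got {code!r}"
                )
    return matrix


def classify_regulation(
    assay: AssayEvidence,
    tf_identification: str,
    readout: str,
    *,
    binding_corroboration: bool = False,
    matrix: Mapping[tuple[str, str], str | None] | None = None,
) -> EvidenceVerdict:
    """Verdict for a transcription-regulation assay via the decision matrix."""
    if assay.assay not in REGULATION_ASSAYS:
        raise WrongCategoryError(f"{assay.assay} is not a transcription-regulation assay")
    if tf_identification not in TF_IDENTIFICATIONS:
        raise ConfigurationError(f"unknown TF identification strategy {tf_identification!r}")
    if readout not in READOUTS:
        raise ConfigurationError(f"unknown readout {readout!r}")
    table = DEFAULT_REGULATION_MATRIX if matrix is None else matrix
    key = (tf_identification, readout)
    if key not in table:
        raise ConfigurationError(f"decision matrix has no entry for {key}")
    mi = assay.mi_code
    if key in _CORROBORATION_REQUIRED and not binding_corroboration:
        return EvidenceVerdict(
            False, "transcription_regulation", None,
            "knock-out/knock-down effects on target mRNA do not by themselves prove "
            "transcription regulation; direct-binding corroboration required", mi,
        )
    code = table[key]
    if code is None:
        return EvidenceVerdict(
            False, "transcription_regulation", None,
            f"TF identification {tf_identification!r} with readout {readout!r} is insufficient", mi,
        )
    return EvidenceVerdict(True, "transcription_regulation", code, "", mi)
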
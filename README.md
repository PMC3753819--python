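# tfcurate

A rule engine for Gene Ontology annotation of sequence-specific DNA-binding
transcription factors (DbTFs).

Biocurators who annotate transcription factors from the experimental
literature face a recurring problem: a protein only qualifies as a DbTF when
two independent capabilities are each demonstrated by an adequate assay —
(i) it binds specific DNA sequences in gene regulatory regions, and (ii) it
participates in RNA polymerase II-dependent regulation of transcription.
Which assays count, which GO evidence code each assay supports, and how the
two separate annotations combine into a composite "transcription factor
activity" annotation are all matters of explicit rules. `tfcurate` encodes
those rules as an executable engine so that curation decisions are
reproducible, checkable and exportable in the standard GAF 2.0 format.

## The model

GO defines composite TF-activity molecular-function (MF) terms by two typed
relations: an activity term *T* `has_part` a DNA-binding MF term *B* and is
`part_of` a transcription-regulation biological-process (BP) term *R*, e.g.

```
GO:0000981 "sequence-specific DNA binding RNAP II transcription factor activity"
    has_part GO:0000977 "RNAP II regulatory region sequence-specific DNA binding"
    part_of  GO:0006357 "regulation of transcription from RNAP II promoter"
```

Given an evidenced binding annotation *b* and regulation annotation *r*, the
engine annotates the **most specific** activity term *T* whose requirements
are fully covered by the evidence — every `has_part` target of *T* (direct
or inherited down `is_a`) must lie at or above *b*, and every `part_of`
target at or above *r*. The "at or above" direction prevents over-claiming:
evidence for regulatory-region binding can never produce a
promoter-proximal activity annotation.

Evidence codes propagate with the inference:

| binding | regulation | same paper | composite record(s) |
|---------|------------|-----------|---------------------|
| IDA | IDA | yes | IDA |
| IMP | IMP | yes | IMP |
| IDA | IMP | yes | IDA + IMP |
| IMP | IDA | yes | IMP + IDA |
| IPI | IDA | yes | IPI + IDA (TF-binding terms only) |
| any | any | no  | IC, citing GO_REF:0000036 with both GO IDs in with/from |

Upstream of inference, assay evidence is classified by golden rule tables:
gel shifts (EMSA) on unverified native extracts are dismissed ("no
evidence") unless rescued by two-sided probe competition or an antibody
supershift; ectopic/purified TF presentations give IDA and mutated-TF
presentations IMP; X-ray structures count only with a protein-DNA
co-crystal; protein-protein assays (two-hybrid, co-purification, co-IP)
support IPI/IDA on TF-binding terms; reporter-gene and target-mRNA assays
map through a configurable decision matrix, with knock-out/knock-down
effects on endogenous mRNA admitted only alongside corroborating
direct-binding evidence. Each admissible assay also carries its PSI-MI
identifier (e.g. EMSA MI:0413, supershift MI:0412).

## Worked example

One record: purified-TF EMSA on a proximal promoter element (paper 1) plus
ectopic-TF reporter activation of target gene NCBI:2353 (paper 2).

```python
import io, sys
from tfcurate import (AssayEvidence, CurationRecord, figure1_subgraph,
                      run_pipeline, write_gaf)

graph = figure1_subgraph().combined()
record = CurationRecord(
    gene_product=("UniProtKB", "P04637", "TP53"),
    taxon="taxon:9606",
    paper_refs=("PMID:1000001", "PMID:1000002"),
    binding_granularity="proximal",
    dna_binding_evidence=(
        AssayEvidence(assay="emsa", variant="purified", reference="PMID:1000001"),
    ),
    regulation_evidence=(
        (AssayEvidence(assay="reporter_gene", reference="PMID:1000002"),
         "ectopic_wt", "reporter_wt_tfbs", "positive"),
    ),
    target_genes=("NCBI:2353",),
)
annotations, report = run_pipeline([record], graph)
write_gaf(annotations, sys.stdout, graph)
```

prints (columns 10–12 and 17 elided here for width):

```
!gaf-version: 2.0
UniProtKB  P04637  TP53    GO:0000978  PMID:1000001    IDA                         F  taxon:9606  20130216  tfcurate
UniProtKB  P04637  TP53    GO:0045944  PMID:1000002    IDA                         P  taxon:9606  20130216  tfcurate  has_regulation_target(NCBI:2353)
UniProtKB  P04637  TP53    GO:0001077  GO_REF:0000036  IC   GO:0000978|GO:0045944  F  taxon:9606  20130216  tfcurate
```

Three annotations: the MF binding annotation (proximal-region
sequence-specific DNA binding, IDA), the BP regulation annotation (positive
regulation of RNAP II transcription, IDA, carrying the target gene as a
`has_regulation_target` extension), and the inferred composite activity
term GO:0001077. Because binding and regulation come from different papers
the composite is an IC record citing GO_REF:0000036 with both contributing
GO IDs in with/from. The report counts `ic_count: 1`.

## Command line

```sh
tfcurate run --records records.tsv --out out.gaf [--obo go.obo] [--config matrix.yaml]
tfcurate validate --gaf out.gaf          # lint mode; exit 1 on violations
tfcurate demo --n 100 --seed 42          # synthetic records + their GAF
```

The curation-record TSV schema is documented in `tfcurate/workflow.py` and
`docs/methods.md`; `tfcurate demo` writes a worked instance of it.

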
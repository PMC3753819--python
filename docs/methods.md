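# Methods

## The curation model

`tfcurate` operationalizes a literature-curation protocol for
sequence-specific DNA-binding transcription factors (DbTFs) of RNA
polymerase II. Its central assumption is that DbTF function is a *composite*
claim: a protein qualifies only when specific DNA binding and participation
in RNAP II transcription regulation are each supported by an admissible
experiment. The two capabilities are annotated separately — a
molecular-function (MF) binding term and a biological-process (BP)
regulation term — and the composite "TF activity" MF annotation is then
*inferred*, never asserted directly from a single experiment.

The inference is driven by the structure of the ontology itself. Every
composite activity term carries `has_part` relations to the binding MF
term(s) it requires and `part_of` relations to the regulation BP process it
serves; both relation kinds propagate down the `is_a` hierarchy. The engine
selects the most specific activity term whose full requirement set is
covered by the evidence:

* every `has_part` target (direct or inherited) is equal to or an `is_a`
  ancestor of the evidenced binding term, and
* every `part_of` target is equal to or an `is_a` ancestor of the evidenced
  regulation term.

The "at or above" direction is the load-bearing choice: it makes the search
conservative, so coarse evidence (e.g. regulatory-region binding of unknown
RNAP II dependence) resolves to a coarse activity term and can never
produce a promoter-proximal claim. Specificity ranking is `is_a`-only;
`part_of`/`has_part` connect GO aspects and do not rank granularity. If two
incomparable terms ever satisfy the constraints the engine emits both and
logs a warning (the bundled subgraph has no such ties).

## The bundled ontology subgraph

The engine needs only a small GO neighbourhood, shipped as a hand-encoded
fixture (`tfcurate.fixtures.figure1_subgraph`), so no ontology download is
required. It has two panels sharing the regulation BP terms:

* **DbTF panel** — binding ladder GO:0043565 → GO:0000976 → GO:0000977 →
  {GO:0000978 proximal, GO:0000980 distal}; regulation terms GO:0006357
  with its positive (GO:0045944) and negative (GO:0000122) children under
  GO:0006355; activity terms GO:0003700 → GO:0000981 → {GO:0000982,
  GO:0003705} → {GO:0001077, GO:0001078, GO:0001205, GO:0001206}.
* **TF-binding panel** — binding terms GO:0008134 → GO:0001085; activity
  terms GO:0000989 → GO:0001076 → {GO:0001190, GO:0001191}, for factors
  whose activity depends on binding another TF rather than DNA.

Per-term provenance is recorded in the fixture (`protocol` vs `go_release`):
IDs not named in the guidelines (the positive/negative BP children, the
negative composite terms GO:0001078/GO:0001206, GO:0003700 and the
TF-binding panel internals) were sourced from a GO release snapshot
contemporary with the protocol (2013-02-16). Two mappings are provisional
design choices with no explicit rule behind them: binding evidence of
unknown RNAP II dependence (GO:0043565/GO:0000976 granularity) resolves to
the generic activity parent GO:0003700, and the `tf_generic` binding
granularity maps to GO:0001085 so the TF-binding inference lands on
GO:0001076.

A full GO OBO file may be substituted (`load_obo_subset`); the loader
resolves alt_ids, rejects obsolete requested terms with a replacement
suggestion, ignores relationship types outside is_a/part_of/has_part with a
warning, and reports line numbers on malformed stanzas. Ontology round
trips (fixture → OBO text → graph) are exercised by the test suite.

## Evidence classification

Admissibility rules are golden tables, not heuristics:

* **Specific DNA binding** (in vitro only; in vivo occupancy such as ChIP
  is out of scope because it cannot distinguish direct DNA contact from
  indirect association). EMSA and supershift carry a TF-presentation
  variant: native extract, ectopic-expression extract, purified TF
  (IDA), or the two mutated-TF presentations (IMP). The unverified
  native-extract EMSA is dismissed; it is rescued to IDA only by *both*
  competition flags (wild-type probe competes the shift away AND a
  TFBS-point-mutant probe fails to) — one-sided competition is not enough —
  or by running the assay as a supershift. Footprinting variants, affinity
  chromatography, pull-down, southwestern blot and SELEX are IDA;
  crystallography is IDA only with a protein-DNA co-crystal. Each assay
  carries its PSI-MI identifier; southwestern blot has none (it is
  MeSH-indexed) and the field stays absent.
* **TF binding** (protein-protein): two-hybrid → IPI; co-purification and
  co-immunoprecipitation → IPI when the interaction partner is identified
  (it populates with/from), else IDA. IPI never applies to DNA-binding
  terms, and the DNA-binding classifier never returns IPI.
* **Transcription regulation**: a decision matrix over (TF identification
  strategy × readout). Shipped default: ectopic wild-type TF → IDA;
  ectopic mutant, knock-down, knock-out → IMP; native identification alone
  → inadmissible. Knock-out/knock-down read out on endogenous target mRNA
  additionally requires the record's `binding_corroboration` flag — such
  experiments do not by themselves prove transcription regulation. The
  matrix cells are a provisional default and can be replaced wholesale via
  a YAML file (`load_regulation_matrix`); the corroboration gate is an
  engine rule and applies regardless of the matrix.

## Evidence propagation and units of output

Per record the engine emits, in order: one MF binding annotation per
admissible binding evidence (with the `contributes_to` qualifier when the
function is exercised only within a complex — the qualifier propagates to
the composite, never to the BP annotation), one BP regulation annotation
per evidenced direction (carrying `has_regulation_target(gene)` extensions
for stated target genes), then the composite annotations.

For each (binding mode × direction) pair the engine prefers a same-paper
binding/regulation evidence pairing when one exists; the composite then
carries the contributing codes as printed in the propagation table (two
records when the codes differ, e.g. IMP binding + IDA regulation). With no
shared reference the composite is a single IC record citing GO_REF:0000036
and both contributing GO IDs in with/from. One IC record is produced per
cross-paper inference; at coarse granularities a both-directions record
yields two IC records on the same composite term with distinct with/from
(positive vs negative regulation term), which is intentional — merging them
would lose which process term contributed. A final most-specific-wins
dedup collapses `is_a`-comparable composites with identical evidence; a
gene product may legitimately keep both a DNA-binding composite and a
TF-binding composite (incomparable terms).

Records may show both positive and negative regulation; the record-level
"both" direction is derived from the presence of both entry directions and
produces both composite children. Emission dates default to a fixed
constant (20130216) so output is reproducible; callers can override.

## Pipeline and validation

`run_pipeline` applies, per record: the species filter (default
human/mouse/rat, taxon:9606/10090/10116, overridable; records with no
identifiable species are rejected with a logged reason), the two-part
qualification check, and annotation building. Failures are isolated per
record — logged, never aborting the batch — and output order is
deterministic. The report conserves totals
(`records_in = filtered_species + disqualified + annotated`) and counts
annotations per evidence code. A record qualifies when at least one binding
verdict (DNA- or TF-binding) and one regulation verdict are admissible;
non-qualifying records still contribute their individual admissible
annotations, never a composite.

`validate_gaf` is the same rule set run in reverse over any GAF 2.0 input:
composite activity annotations must have same-object binding and
regulation support consistent with their has_part/part_of requirements; IC
records must cite GO_REF:0000036 with two GO IDs; IPI must sit on
TF-binding-related terms; `contributes_to` only on aspect F; aspects must
match term namespaces. Pipeline output validates clean by construction
(checked in the test suite).

GAF output is dialect 2.0, 17 columns, `|` within-column separator, `,`
between annotation extensions; round trips are byte-exact. GAF 2.2
qualifier vocabulary and GPAD/GPI are out of scope.

## Synthetic data

The generator (`generate_records`) emulates a small-scale curation batch:
a species mixture (50% human, 22% mouse, 13% rat, 8% out-of-scope, 7%
unidentifiable), binding granularities weighted toward the informative
middle of the ladder, regulation directions including 15% both-direction
records, 30% cross-paper evidence splits, 15% dismissible native-extract
EMSAs, 10% inadmissible regulation evidence, 20% TF-binding evidence, 10%
complex-subunit (`contributes_to`) records and target genes on half the
records. Weights were chosen once as plausible for curated TF literature;
they are a `RecordProfile` and fully overridable. Gene products use an
obviously fake namespace (`FAKEDB:SYNTFnnnnn`) to prevent misreading as
real curation.

Each record carries planted ground truth (`RecordTruth`): whether it
qualifies, its expected composite terms from a frozen flat lookup table
(deliberately independent of the graph search), and its expected IC count
(one per cross-paper inference = binding mode × direction). What the
generator does **not** emulate: free-text ambiguity, curator disagreement,
multi-gene papers, conflicting evidence within a record, or realistic
identifier namespaces — so passing tests demonstrate rule-engine
correctness, not robustness to messy real literature.

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline on batches of
1000 generated records (~3000 annotations), enumerate all 44 valid
(mode × granularity × direction) inference combinations against the
brute-force oracle, and classify every rule-table row; these sizes exercise
every rule path with comfortable margin. All randomness flows through a
single integer seed (numpy `default_rng`); identical inputs give identical
outputs. There are no floating-point computations anywhere in the engine —
all decisions are exact set and table operations — so no tolerances apply.

## Known limitations

* Regulation decision-matrix cells are provisional defaults, not published
  values; override via YAML for site conventions.
* The bundled subgraph is a snapshot; term names and the TF-binding branch
  have since been reorganized in GO, and annotations produced against the
  fixture reflect the snapshot's semantics.
* The curation-record TSV is this package's own exchange format (the
  protocol it implements defines none); the schema is documented in
  `workflow.py`.
* No support for GAF 2.2 qualifiers, GPAD/GPI, isoform (column 17)
  semantics beyond pass-through, or high-throughput PPI ingestion.
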
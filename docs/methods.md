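# Methods

## Scope and data model

`neurokg` turns heterogeneous per-study CSV exports (demographics,
neuropsychological assessment scores, image-derived volumes) into a single
OWL/RDF knowledge graph aligned with OBO Foundry vocabularies, selects
cohorts from that graph with SPARQL, and runs a stratified volumetric group
comparison. The package operates strictly downstream of image processing:
it consumes tabular FSL-style outputs (regional volumes and total
intracranial volume in mm³) and never touches images.

The instance pattern per subject is fixed and small:

| node | class | linked by |
|---|---|---|
| subject | NCBITaxon:9606 *Homo sapiens* (+ PD / HC application class) | — |
| role | OBI:0000097 *study subject role* | RO:0000052 *inheres in* → subject |
| identifier | application class *pseudonymous subject identifier* | IAO:0000219 *denotes* → subject; `rdfs:label` carries the pseudonym |
| brain, left/right hippocampus | application anatomy classes | BFO:0000050 *part of* chain up to the subject |
| assay (MoCA; fluency subtest as a part) | NPT:0020000 / app subtest class | BFO:0000057 *has participant* → subject |
| measurement datum | IAO:0000109 | OBI:0000299 *has specified output* from the assay; OBI:0001938 → value specification (OBI:0001933); OBI:0002135 carries the literal |
| feature-extraction process | app process classes | OBI:0000293 specified input (image, IAO:0000101); output datum IAO:0000136 *is about* the hippocampus/brain instance |

Assessment scores are typed `xsd:integer`, volumes `xsd:decimal`. Missing
cells emit no triples — absence is represented by absence, not sentinels.

## Application ontology and namespaces

Application terms live under `https://w3id.org/neurokg/onto/` with `NKG_`
numeric local ids; instance IRIs under `https://w3id.org/neurokg/instance/`.
Term definitions follow one axiom pattern: named superclasses plus
existential (`some`) restrictions — the only quantifier the modelled
process definitions need. Example: *right hippocampal volume feature
extraction using the FIRST segmentation utility from FSL on a T1 MRI image*
has two named parents (OBI *planned process*; the generic right-hippocampal
extraction term) and three restrictions (specified input *some* image;
specified output *some* right hippocampal volume measurement datum;
achieves *some* feature extraction objective).

Two groups of terms are deliberately application-namespace stand-ins rather
than canonical imports: the anatomy classes (brain, hippocampi — FMA is far
too large to vendor, and only the parthood skeleton is needed) and the
*feature extraction objective*. The term registry maps labels/CURIEs to
IRIs, so swapping a stand-in for a canonical term is a one-line registry
change. A minimal hand-built Turtle module of the OBO terms used (labels +
shallow subclass skeleton) is vendored so that nothing is downloaded;
loading full ontology releases on top is supported.

## Ontology operations

* **Module extraction** is plain recursive reference closure: seeds plus
  every IRI reachable through member axioms (walking restriction blank
  nodes), keeping all triples rooted at members. It is monotone in the seed
  set and idempotent; it is *not* a syntactic-locality (SLME) extractor and
  performs no reasoning — sufficient for the vendored mini-ontologies it is
  applied to.
* **Merging** is RDF set union.
* **Canonical serialization** uses canonical blank-node labelling followed
  by sorted N-Triples, making whole-pipeline determinism testable by byte
  comparison. Instance IRIs are deterministic suffixes of the subject IRI
  (role, brain, assay, datum, …), so re-ingestion is idempotent and the
  instance graph is blank-node-free.

## Harmonization and pseudonymization

Field mappings are `(source, header) → pattern key` entries with a value
type, an optional valid range, and an optional value recoding map (e.g.
`1→PD, 2→HC` for coded diagnosis columns). Harmonization is
total-with-report: every header is either mapped or listed as unmapped;
out-of-range cells (MoCA total outside [0, 30], negative volumes, …) are
quarantined to an exceptions report and never ingested. Only the MoCA total
and category-fluency keys ship mapped by default — they are the only
instruments shared by both emulated sources; other instruments are
admissible keys left unmapped, since cross-instrument score aggregation is
out of scope.

Subject IRIs embed a truncated keyed BLAKE2b HMAC of (source, raw id) under
a configurable salt. Identical inputs always mint the same IRI; different
salts decouple linkage; the raw identifier never appears in the IRI (a rare
accidental hex-substring hit triggers a deterministic re-digest). The two
emulated cohorts are assumed disjoint — no cross-source record linkage is
attempted.

## Cohort selection and defined classes

The cohort query template binds subject → role → identifier → assay →
datum → value specification → score and filters the bound score variable
with a comparator ({<, ≤, ≥, >}) and threshold. Class-membership checks are
written as `FILTER EXISTS` over already-bound nodes — semantically
identical to inline `rdf:type` patterns, but it prevents naive bottom-up
evaluators from cross-joining the type patterns (rdflib's evaluator orders
patterns by bound-term count, which otherwise makes the query cubic in
cohort size). "Direct type" is expressed portably as `rdf:type` plus a
`FILTER NOT EXISTS` excluding strict-subclass matches, instead of a
store-specific predicate.

Defined cohort classes (e.g. *study subject with mild cognitive
impairment*: MoCA total < 26, strict, matching the conventional threshold)
are materialized by rule: the query's subject set receives explicit
`rdf:type` assertions. Materialization is idempotent and definitionally
equivalent to the query — full OWL datatype-restriction classification is a
triple-store feature, not replicated here.

## Statistics

Normalized volume is the exact quotient volume/ICV (dimensionless).
Subjects are stratified into PD below threshold (MoCA < 26), PD at/above,
and HC (never split by score); subjects missing group or score are excluded
and reported. The omnibus test is a fixed-effects one-way ANOVA computed
from sums of squares, with the p-value from the F(k−1, N−k) distribution;
Fisher's LSD computes all pairwise t statistics with the ANOVA's pooled
within-group mean square and N−k degrees of freedom, two-sided, with no
multiplicity adjustment (that is the definition of LSD). LSD is computed
and reported regardless of omnibus significance, alongside the omnibus p.
Degenerate inputs are flagged rather than hidden: zero within-group
variance with unequal means reports F = +∞, p = 0; groups with n < 2 are
rejected.

By default the *bilateral* (left + right) hippocampal volume enters the
comparison — both sides are modelled in the graph and the clinical question
concerns hippocampal volume generally — with a flag for single-side
analyses. p-values come from the classical F and t distributions, not
permutation, matching the named tests.

## Synthetic cohort generator

The generator emulates the study design end to end: two sources with fully
disjoint header dialects (verbose `MOCA_words_total`-style vs terse
`MCAVF`-style, including coded group/sex values and one deliberately
unmapped instrument column per source), each with PD and HC groups. The
`table1` preset encodes the published per-group margins: group sizes
29/21/69/31, % female, mean age, mean education, mean Hoehn–Yahr stage, and
mean MoCA totals (25.0/26.6/26.9/28.1). Only means are published, so
standard deviations are package defaults chosen for realism (age 8–9 y,
education 2.5 y, MoCA 2–3 points, H&Y 0.5–0.6).

MoCA and stratum are generated jointly: the sub-threshold stratum is drawn
first (either an exact planted count or a Bernoulli draw whose probability
is the rounded-Gaussian mass below 26), then the integer score from the
stratum-conditional truncated Gaussian. This makes sub-threshold counts
plantable exactly — the `cohort_demo` preset plants 78 + 32 = 110
sub-threshold subjects across the two sources so the cohort query has a
known closed-form answer. That preset enlarges the first source (PD 100 /
HC 30), because 78 sub-threshold subjects cannot exist in a 50-subject
source; the published sizes stay in `table1`.

No volume summaries are published, so volume priors are plausibility
defaults: per-side hippocampus 𝒩(3700, 350²) mm³, ICV 𝒩(1.48×10⁶,
(1.3×10⁵)²) mm³, ICV redrawn if it fails to dominate the structure volumes.
Sub-threshold PD subjects receive a standardized per-side volume deficit
(δ = 0.8 by default, in units of the per-side volume SD). Because ICV noise
is independent, the effective standardized effect on the normalized ratio
is somewhat smaller (≈ 0.7); the planted-effect checks test ordering
recovery and power against this effective effect. Hoehn–Yahr is emitted as
a demographic column only and drives no computation.

What the generator does *not* emulate: item-level assessment data,
longitudinal visits, site/scanner effects, missingness mechanisms beyond
explicit blanks, demographic–volume correlations (age and volume are drawn
independently), and measurement error models for segmentation. Passing
tests therefore demonstrate the correctness of the integration, query, and
statistical machinery under the stated distributional assumptions — not
robustness to real-data pathologies.

## Numerical and design choices

* Strict `<` for the impairment threshold; complementary `≥` selection is
  available, and the two partition the scored subjects exactly.
* The aboutness link between a volume measurement datum and the anatomy
  instance uses IAO:0000136 (*is about*).
* HC subjects scoring below 26 stay in the single HC stratum; only the PD
  group is stratified.
* One baseline assay per subject is emitted, so cohort rows are one per
  subject; retest handling is out of scope.
* Simulation-based checks use scaled problem sizes chosen to keep the whole
  suite fast: 50 cohorts × 20 subjects for query/oracle equivalence, 2000
  replicates at the published group sizes for the null rejection rate, 300
  for ordering recovery.
* Exit codes: 0 success, 2 pattern-conformance violations (unless
  `--allow-violations`), 3 configuration errors.

## Known limitations

* No OWL-DL reasoning or classification; inference is limited to
  SPARQL-expressible rule materialization.
* The vendored vocabulary module carries only labels and a shallow subclass
  skeleton, not the full axiomatization of OBI/IAO/NPT.
* SHACL shapes are exported for interoperability but validation runs
  through the built-in rule checker, not an external SHACL engine.
* The rdflib in-memory store is the only backend; swapping in a server-side
  triple store would require only re-pointing query execution.
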
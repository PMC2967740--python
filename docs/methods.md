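# Methods

## Rule representation

A decision-support rule is `IF <condition tree> THEN <statements>`. The
antecedent grammar is explicit AND/OR/NOT over typed leaf predicates
(`MEDICATION_ACTIVE`, `MEDICATION_CONSIDERED`, `TAKING_DRUG_IN_CLASS`,
`HAS_DISEASE`, `HAS_VARIANT`, `HAS_PHENOTYPE_CLASS`, `TUMOR_HAS_MUTATION`,
`AGE_COMPARE`, `LAB_COMPARE`). Source material states such rules in prose;
fixing a closed grammar makes two things mechanical: evaluation against a
patient record, and extraction of the clinical-data requirements
(`antecedent_fields`), which the coverage analysis consumes. Every leaf
condition reads exactly one `ClinicalDataField` (tagged with its kind and
its source system — inpatient/outpatient DB, laboratory DB, or supporting
knowledge). Conditions on derived classes additionally carry an
`sk_requirement` field naming the piece of supporting knowledge they depend
on (a phenotype-class definition or a drug-class membership list); this is
what lets a requirement set list, e.g., both "CYP2C9 variant status" (lab)
and "CYP2C9 variants causing poor metabolism" (supporting knowledge) for a
single poor-metabolizer condition.

Star-allele diplotypes are normalized to `*a/*b` with alleles ascending
numerically; a single-allele condition (`HAS_VARIANT(CYP2C9, *2)`) matches
either chromosome, a diplotype condition matches exactly, and a
`HAS_VARIANT` condition with no named allele means "any non-`*1` allele".
Drug names are matched as normalized lowercase generic names; brand names
resolve through an editable two-column synonym TSV.

Catalog interchange is versioned YAML (JSON loads too, YAML being a
superset), with `format_version` required and unknown versions rejected.
`save → load` is the identity on every field, and serialization is a
fixpoint (`dumps(loads(dumps(c))) == dumps(c)`), which the round-trip tests
exercise on both fixtures and 50-rule synthetic catalogs. Validation
returns violations as data (stable codes like `MISSING_CONSEQUENT`,
`INCOMPLETE_PREDICATE_ARGS`, `DUPLICATE_RULE_ID`) rather than raising, so a
curation pass can report everything at once.

## Presentation-type classification

How an alert should be presented tracks how actionable the statement is.
The decision procedure for one statement is:

1. consequences specified (curator flag) → **WARNING**, any certainty;
2. else clear action (curator annotation) stated with medium-to-high
   certainty language → **RECOMMENDATION**;
3. else → **INFORMATION**.

Certainty is read from the text with two small lexicons — low
`{might, may, could}`, medium/high `{should, will, are, is, must, was, do}`
— using case-insensitive whole-word matching (no substring hits: "Maybe"
does not contain the token "may"). The ordering of steps realizes the
severity tie-breaks (warning beats recommendation beats information).

Choices where the procedure was genuinely underdetermined:

- **Mixed certainty**: when low and high terms co-occur, LOW wins. Hedged
  language downgrades actionability; this is the conservative reading and
  the alternative is a one-line change in `extract_certainty`.
- **"Clear action"** is a curator annotation (`action_specificity`), not a
  lexical inference: CLEAR requires a concrete executable instruction (a
  dose, a named test, a contraindication). A directionless "the dose should
  be adjusted" is VAGUE — which is exactly what keeps the atomoxetine
  worked rule at INFORMATION despite its "should".
- **Consequence detection** is likewise an explicit flag; a configurable
  consequence lexicon (`risk, caution, adverse, toxicity, bleeding, fatal`)
  only *suggests* candidates for review and never sets the flag.
- **Multi-statement rules** classify as the maximum severity across their
  statements: an alert must not understate risk.
- **Percentages** everywhere round half away from zero to integers (the
  shared `rounding.pct`). One consequence worth knowing: 49/251 = 19.52%
  rounds to 20, so a source that prints 19% for that ratio disagrees with
  every uniform convention that fits the other published category
  percentages; the tests pin 20 and the discrepancy is deliberate.

## Supporting-knowledge inference

Supporting-knowledge rules are datalog-style clauses: a conjunction of fact
patterns (variables allowed) with optional guards (numeric comparisons,
allele-containment), deriving one fact template whose variables must all be
bound by the premises (`UNBOUND_DERIVATION` otherwise). Facts are ground
and positive-only — no negation-as-failure, no retraction — so the closure
under a rule set is a unique least fixpoint, computed by repeated rounds
until stable with a hard safety cap (10,000 rounds → `DERIVATION_LIMIT`).
Idempotence, monotonicity in base and rules, order independence, and
agreement with a naive repeated-scan oracle are all tested on random
propositional rule sets.

OR in the interchange format is normalized into multiple clauses at load
and NOT is rejected, preserving the fixpoint guarantee. Drug-class
membership TSVs compile into one ground clause per member drug
(`IF medication_active(d) THEN taking_drug_in_class(c)`). The packaged
diplotype→phenotype tables and class membership lists are **illustrative
placeholders** covering the worked examples; they are not clinically
authoritative and are meant to be replaced by institutional content.

## Three-valued evaluation

Patient records are chronically incomplete, and the coverage question
hinges on distinguishing "absent" from "negative". Conditions evaluate to
TRUE/FALSE/UNKNOWN: UNKNOWN when the record carries no data for the field
(a `None` collection, or a gene missing from the genotype map), FALSE when
data is present but unsatisfying. Antecedents combine under strong Kleene
logic — FALSE dominates AND, TRUE dominates OR, NOT preserves UNKNOWN — so
"not on the drug, genotype never measured" is definitively NOT_FIRED
(FALSE ∧ UNKNOWN = FALSE) while "on the drug, genotype never measured" is
INDETERMINATE with the genotype field named. Rules never fire on UNKNOWN
(patient-safety conservative default). A fired rule emits one combined
alert joining its consequent statements (the one-alert-per-statement
alternative was considered and rejected to avoid double alarms from a
single trigger); catalog alerts sort severity-first, ties by rule id. Lab
comparisons require exact unit agreement and raise `UNIT_MISMATCH` rather
than guess at conversion.

## Coverage analysis

An `EMRCapabilityProfile` maps fields to one of eight availability
statuses; exact field-id entries beat (kind, detail-glob) patterns, and two
patterns matching one field with different statuses raise
`PROFILE_CONFLICT` rather than silently pick one. The three scenarios are
strictly nested — EMR alone satisfies `{DISCRETE}`; + knowledge adds
`REQUIRES_SUPPORTING_KNOWLEDGE`; + expansion adds the four
feasible-expansion statuses (disease-status definitions,
pathology/microbiology fields, parseable free text) — so executable counts
are provably non-decreasing. `REQUIRES_FULL_NLP` and `ABSENT` are
satisfiable in no scenario, which is what caps achievable coverage below
100% when present.

Attribution counts a rule toward blocking category C iff it needs ≥1 field
of status C and is not executable under the knowledge scenario. The default
(`any`) counts a rule under every blocking category it needs, reading
"lack of access would inhibit execution" literally; a `sole` mode counts
only unique blockers. Both are exposed because the choice changes overlap
behavior and neither is canonical.

## Synthetic data

Generators are pure functions of a `GeneratorSpec` (seed, n, mix
overrides); one `random.Random` stream per call, no global state. Default
mixes are the study conditions the package emulates: presentation
39/39/22 information/recommendation/warning; category mix with 24% benefit
prediction, 13% testing guidance, 9% coadministration, 4% patient
communication and the remaining 50% split 20/15/15 across dose adjustment,
monitoring and pre-treatment consideration (the published figure groups
those three); an availability mix (45% discrete, 20% requiring supporting
knowledge, 28% across the four expansion types, 7% never satisfiable)
chosen so that, as in practice, roughly a third of rules run on discrete
data alone, about half run with supporting knowledge, and a hard ceiling
remains below 100%.

Synthetic catalogs *plant* their ground truth rather than sample outcomes:
each rule's consequent text and annotations are constructed so the
classifier provably assigns the planted label, and each antecedent field
carries a planted availability status; all of it is stored in catalog
metadata, so recovery tests compare exactly, not statistically.
`gen_citation_sets(n_a, n_b, n_shared, seed)` plants exactly `n_shared`
shared identifiers; `gen_publications` plants exact per-category tag
counts on random subsets. What the generators do **not** emulate: realistic
prose (texts are templated), correlated comorbidities/polypharmacy,
linkage between star alleles, or free-text lab values — so green tests
demonstrate the machinery is correct under known ground truth, not that
real-label curation would reproduce any particular percentage.

## Problem sizes and determinism

The shipped test and acceptance runs use five worked rules, 251/28-record
publication sets, 200 random rule sets for the fixpoint oracle, 1,000
8-rule catalog/profile pairs for coverage properties, and a 200-rule
catalog for plant-and-recover; all are seeded and complete in seconds. The
headline curation statistics of the motivating study (its 106-rule catalog
and institution-specific EMR profile) were never published, so they are
covered by these property and plant-and-recover suites rather than numeric
reproduction; the encoded-knowledge matrix fixture ships the 30 printed
drug rows verbatim.

## Known limitations

- No negation or retraction in supporting knowledge; phenotype calling is
  exact-diplotype lookup, not activity scores.
- No terminology integration (RxNorm/SNOMED); drug and disease matching is
  normalized-string plus a synonym table.
- The certainty lexicons are deliberately tiny and English-only; negation
  scope ("should not") is out of scope — curator annotations carry that
  burden.
- Unit handling for labs is exact-match, by design.
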
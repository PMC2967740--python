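# pgxcds

Rule-based pharmacogenomic (PGx) clinical decision support as a testable
Python library.

Drug labels carry PGx guidance ("reduce the dose of celecoxib by 50% in
CYP2C9 poor metabolizers") that is written for humans, not machines. To
surface that guidance at the point of care, each actionable passage must be
(1) expressed as a computable if-then rule, (2) classified by how actionable
it is — *information only*, *recommendation*, or *warning* — so the alert
matches the strength of the statement, and (3) checked against what an
institution's EMR can actually supply: a rule is only useful if the clinical
data in its IF-part exists in computable form. `pgxcds` implements that
whole pipeline for informaticists building or auditing PGx alerting:

- **`rule_model`** — typed if-then rules: an antecedent condition tree
  (AND/OR/NOT over predicates such as `MEDICATION_ACTIVE`, `HAS_VARIANT`,
  `HAS_PHENOTYPE_CLASS`, `AGE_COMPARE`) in which every leaf reads exactly
  one clinical-data field, plus annotated consequent statements; versioned
  YAML interchange with round-trip identity.
- **`certainty_classifier`** — presentation-type assignment. A statement is
  a WARNING if potential consequences are specified; a RECOMMENDATION if a
  clear action is stated with medium-to-high-certainty language
  (*should, will, are, is, must, was, do*); otherwise INFORMATION
  (including actions hedged with *might, may, could*). Ties resolve to the
  higher severity: warning > recommendation > information.
- **`knowledge_engine`** — forward-chaining closure over supporting-
  knowledge rules that derive intermediate facts from raw data, e.g.
  `IF genotype(CYP2C9, *2/*3) THEN poor metabolizer` or
  `IF age < 18 THEN child`. Ground, positive-only facts give a unique least
  fixpoint.
- **`rule_evaluator`** — patient-level evaluation under strong Kleene
  three-valued logic. Missing data is UNKNOWN, not false; a rule fires only
  when its antecedent is definitely TRUE, and an INDETERMINATE result names
  the blocking fields.
- **`coverage_analyzer`** — the fraction of a catalog executable against an
  EMR capability profile under three nested scenarios (EMR alone, EMR +
  supporting knowledge, EMR + feasible expansion), with blocking-category
  attribution.
- **`evidence_catalog`** — citation-set overlap (percentage over the
  union), CO/PD/PK/FA/GN evidence-category distributions for multi-tagged
  publications, and a per-drug encoded-knowledge matrix.
- **`synthetic_data` / `fixtures`** — seeded generators (catalogs with
  planted labels/categories/availability statuses, patients with
  configurable allele frequencies, capability profiles, citation sets with
  an exact planted intersection) plus packaged worked-example fixtures:
  five fully specified rules, the warfarin/CYP2C9 rule, and a 30-drug
  encoded-knowledge matrix.

## Worked example

```python
from pgxcds import (PatientRecord, table2_rules, default_supporting_knowledge,
                    evaluate_catalog)

patient = PatientRecord(
    "pt-001",
    age=62,
    medications_active={"celecoxib", "codeine sulfate"},
    medications_considered={"fluoxetine hcl"},
    germline_genotypes={"CYP2C9": "*2/*3"},
)
result = evaluate_catalog(table2_rules(), patient, default_supporting_knowledge())
print(result.render())
```

prints

```
[WARNING] fluoxetine-cyp2d6-coadministration: coadministration should be approached with caution
[RECOMMENDATION] celecoxib-cyp2c9-pm-dose: the dose of Celecoxib should be reduced by 50%

atomoxetine-cyp2d6-dose: NOT_FIRED
celecoxib-cyp2c9-pm-dose: FIRED
clopidogrel-cyp2c19-pm-dose: NOT_FIRED
fluoxetine-cyp2d6-coadministration: FIRED
imatinib-ckit-asm-dose: NOT_FIRED
```

The knowledge engine derived `poor_metabolizer(CYP2C9)` from the `*2/*3`
diplotype, so the celecoxib dose-reduction rule fired as a RECOMMENDATION;
starting fluoxetine while the patient takes a CYP2D6 substrate (codeine)
fired the coadministration WARNING, which sorts first. The imatinib rule
did not fire (no disease/tumor match: FALSE dominates AND even though other
data are missing), and alerts are emitted only for definite matches.

The same pipeline is scriptable from a shell:

```
pgxcds classify --rules rules.yaml         # presentation-type distribution
pgxcds evaluate --rules rules.yaml --patient patient.json
pgxcds coverage --rules rules.yaml --profile emr_profile.yaml
pgxcds overlap  --set-a fda.txt --set-b pharmgkb.txt
pgxcds simulate rules --seed 7 --n 100
pgxcds validate --rules rules.yaml
```

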
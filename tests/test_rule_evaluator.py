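"""Three-valued evaluation: Kleene laws, worked rule scenarios, catalog runs."""

import pytest

from pgxcds.errors import EmptyCatalogError, UnitMismatchError
from pgxcds.knowledge_engine import FactBase
from pgxcds.rule_evaluator import (
    TV,
    PatientRecord,
    Status,
    eval_condition,
    evaluate_catalog,
    evaluate_rule,
    kleene_and,
    kleene_not,
    kleene_or,
)
from pgxcds.rule_model import (
    ClinicalDataField,
    Condition,
    FieldKind,
    FieldSource,
    Predicate,
    PresentationType,
    RuleCatalog,
)
from pgxcds.synthetic_data import GeneratorSpec, gen_patient, gen_rule_catalog

T, F, U = TV.TRUE, TV.FALSE, TV.UNKNOWN


class TestKleeneLogic:
    # hand-enumerated strong-Kleene tables
    AND_TABLE = {
        (T, T): T, (T, F): F, (T, U): U,
        (F, T): F, (F, F): F, (F, U): F,
        (U, T): U, (U, F): F, (U, U): U,
    }
    OR_TABLE = {
        (T, T): T, (T, F): T, (T, U): T,
        (F, T): T, (F, F): F, (F, U): U,
        (U, T): T, (U, F): U, (U, U): U,
    }
    NOT_TABLE = {T: F, F: T, U: U}

    def test_and_matches_enumerated_table(self):
        for (a, b), want in self.AND_TABLE.items():
            assert kleene_and([a, b]) is want, (a, b)

    def test_or_matches_enumerated_table(self):
        for (a, b), want in self.OR_TABLE.items():
            assert kleene_or([a, b]) is want, (a, b)

    def test_not_matches_enumerated_table(self):
        for a, want in self.NOT_TABLE.items():
            assert kleene_not(a) is want

    def test_connectives_commute_and_de_morgan(self):
        for a in TV:
            for b in TV:
                assert kleene_and([a, b]) is kleene_and([b, a])
                assert kleene_or([a, b]) is kleene_or([b, a])
                assert kleene_not(kleene_and([a, b])) is kleene_or([kleene_not(a), kleene_not(b)])


def _field(fid, kind=FieldKind.MEDICATION, source=FieldSource.INPATIENT_OUTPATIENT_DB):
    return ClinicalDataField(fid, kind, source)


class TestEvalCondition:
    def test_active_medication_true(self):
        cond = Condition.make(Predicate.MEDICATION_ACTIVE, {"drug": "warfarin"}, _field("med"))
        pt = PatientRecord("p", medications_active={"Warfarin"})
        assert eval_condition(cond, pt, FactBase()) is T

    def test_missing_gene_is_unknown(self):
        cond = Condition.make(
            Predicate.HAS_VARIANT,
            {"gene": "CYP2C9", "allele": "*2"},
            _field("v", FieldKind.GERMLINE_VARIANT_STATUS, FieldSource.LABORATORY_DB),
        )
        pt = PatientRecord("p", germline_genotypes={"CYP2D6": "*1/*4"})
        assert eval_condition(cond, pt, FactBase()) is U

    def test_age_comparison_false_when_data_present(self):
        cond = Condition.make(
            Predicate.AGE_COMPARE,
            {"comparator": "<", "threshold": 18},
            _field("age", FieldKind.DEMOGRAPHIC),
        )
        assert eval_condition(cond, PatientRecord("p", age=25), FactBase()) is F
        assert eval_condition(cond, PatientRecord("p", age=12), FactBase()) is T
        assert eval_condition(cond, PatientRecord("p"), FactBase()) is U

    def test_diplotype_exact_match(self):
        cond = Condition.make(
            Predicate.HAS_VARIANT,
            {"gene": "CYP2C9", "diplotype": "*3/*2"},
            _field("v", FieldKind.GERMLINE_VARIANT_STATUS, FieldSource.LABORATORY_DB),
        )
        pt = PatientRecord("p", germline_genotypes={"CYP2C9": "*2/*3"})
        assert eval_condition(cond, pt, FactBase()) is T

    def test_lab_unit_mismatch_raises(self):
        cond = Condition.make(
            Predicate.LAB_COMPARE,
            {"analyte": "inr", "comparator": ">", "threshold": 3.0, "units": "ratio"},
            _field("lab", FieldKind.LAB_VALUE, FieldSource.LABORATORY_DB),
        )
        pt = PatientRecord("p", lab_values={"inr": (3.5, "percent")})
        with pytest.raises(UnitMismatchError):
            eval_condition(cond, pt, FactBase())


class TestWarfarinScenarios:
    def test_fires_with_warning_for_carrier_on_drug(self, warfarin, sk_rules):
        pt = PatientRecord("p", medications_active={"warfarin"}, germline_genotypes={"CYP2C9": "*1/*2"})
        status, alert = evaluate_rule(warfarin, pt, sk_rules)
        assert status.value is Status.FIRED
        assert alert.presentation_type is PresentationType.WARNING
        assert "increased bleeding risk" in alert.message

    def test_missing_genotype_blocks_with_named_field(self, warfarin, sk_rules):
        pt = PatientRecord("p", medications_active={"warfarin"}, disease_statuses=set())
        status, alert = evaluate_rule(warfarin, pt, sk_rules)
        assert status.value is Status.INDETERMINATE
        assert alert is None
        assert {f.field_id for f in status.missing_fields} == {"cyp2c9_variant_status"}

    def test_false_and_unknown_is_not_fired(self, warfarin, sk_rules):
        # not on the drug, genotype never measured: FALSE ∧ UNKNOWN = FALSE
        pt = PatientRecord("p", medications_active=set())
        status, _ = evaluate_rule(warfarin, pt, sk_rules)
        assert status.value is Status.NOT_FIRED

    def test_noncarrier_on_drug_not_fired(self, warfarin, sk_rules):
        pt = PatientRecord("p", medications_active={"warfarin"}, germline_genotypes={"CYP2C9": "*1/*1"})
        assert evaluate_rule(warfarin, pt, sk_rules)[0].value is Status.NOT_FIRED

    def test_adding_data_resolves_indeterminacy_monotonically(self, warfarin, sk_rules):
        # resolving an UNKNOWN never creates a new UNKNOWN
        pt = PatientRecord("p", medications_active={"warfarin"})
        assert evaluate_rule(warfarin, pt, sk_rules)[0].value is Status.INDETERMINATE
        pt_full = PatientRecord(
            "p", medications_active={"warfarin"}, germline_genotypes={"CYP2C9": "*2/*3"}
        )
        assert evaluate_rule(warfarin, pt_full, sk_rules)[0].value is Status.FIRED


class TestWorkedCatalogScenarios:
    def test_atomoxetine_fires_through_supporting_knowledge(self, worked_catalog, sk_rules):
        rule = worked_catalog.rules[3]
        pt = PatientRecord(
            "p",
            medications_active={"atomoxetine", "paroxetine"},
            disease_statuses=set(),
            germline_genotypes={"CYP2D6": "*1/*1"},
        )
        status, alert = evaluate_rule(rule, pt, sk_rules)
        assert status.value is Status.FIRED
        assert alert.presentation_type is PresentationType.INFORMATION

    def test_fluoxetine_coadministration_warning(self, worked_catalog, sk_rules):
        rule = worked_catalog.rules[4]
        pt = PatientRecord(
            "p",
            medications_active={"codeine sulfate"},
            medications_considered={"fluoxetine hcl"},
        )
        status, alert = evaluate_rule(rule, pt, sk_rules)
        assert status.value is Status.FIRED
        assert alert.presentation_type is PresentationType.WARNING


class TestEvaluateCatalog:
    def test_alerts_sorted_severity_first(self, worked_catalog, sk_rules):
        pt = PatientRecord(
            "p",
            medications_active={"celecoxib", "codeine sulfate"},
            medications_considered={"fluoxetine hcl"},
            germline_genotypes={"CYP2C9": "*2/*3"},
        )
        result = evaluate_catalog(worked_catalog, pt, sk_rules)
        types = [a.presentation_type for a in result.alerts]
        assert types == sorted(types, key=lambda t: -t.severity)
        assert types[0] is PresentationType.WARNING

    def test_no_matching_rules_yields_no_alerts(self, worked_catalog, sk_rules):
        pt = PatientRecord("p", medications_active=set(), medications_considered=set())
        result = evaluate_catalog(worked_catalog, pt, sk_rules)
        assert result.alerts == []
        assert all(s.value in (Status.NOT_FIRED, Status.INDETERMINATE) for s in result.statuses.values())

    def test_every_alert_comes_from_a_fired_rule(self, worked_catalog, sk_rules):
        pt = gen_patient(GeneratorSpec(seed=5))
        result = evaluate_catalog(worked_catalog, pt, sk_rules)
        assert len(result.alerts) <= len(worked_catalog.rules)
        for alert in result.alerts:
            assert result.statuses[alert.rule_id].value is Status.FIRED

    def test_empty_catalog_rejected(self, sk_rules):
        with pytest.raises(EmptyCatalogError):
            evaluate_catalog(RuleCatalog(rules=[]), PatientRecord("p"), sk_rules)

    def test_matches_per_rule_loop_oracle_on_synthetic_catalog(self, sk_rules):
        catalog = gen_rule_catalog(GeneratorSpec(seed=13, n=100))
        for pt_seed in (1, 2, 3):
            pt = gen_patient(GeneratorSpec(seed=pt_seed))
            batch = evaluate_catalog(catalog, pt, sk_rules)
            for rule in catalog.rules:  # independent single-rule loop
                status, _ = evaluate_rule(rule, pt, sk_rules)
                assert batch.statuses[rule.rule_id] == status
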
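"""Packaged worked-example fixtures.

Five fully specified decision-support rules (imatinib, celecoxib,
clopidogrel, atomoxetine, fluoxetine), the warfarin/CYP2C9 rule, and the
30-drug encoded-knowledge matrix.  These are transcriptions of published
example rules; the curator annotations (action specificity, consequence
flag) are part of the fixture.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .evidence_catalog import AvailabilityClass, KnowledgeMatrix
from .rule_model import (
    ActionSpecificity,
    And,
    ClinicalDataField,
    Condition,
    DrugSynonyms,
    FieldKind,
    FieldSource,
    Or,
    PGxRule,
    Predicate,
    RuleCatalog,
    SupportCategory,
    ThenStatement,
)


def data_path(name: str) -> Path:
    """Path to a packaged data file."""
    return Path(str(resources.files("pgxcds").joinpath("data", name)))


def default_synonyms() -> DrugSynonyms:
    return DrugSynonyms.from_tsv(data_path("drug_synonyms.tsv"))


# ---------------------------------------------------------------------------
# shared clinical-data fields (ids stable across rules in one catalog)

_MEDICATION_LIST = ClinicalDataField(
    "medication_list", FieldKind.MEDICATION_LIST, FieldSource.INPATIENT_OUTPATIENT_DB, "active medication list"
)
_CYP2C9_STATUS = ClinicalDataField(
    "cyp2c9_variant_status", FieldKind.GERMLINE_VARIANT_STATUS, FieldSource.LABORATORY_DB, "CYP2C9"
)
_CYP2C19_STATUS = ClinicalDataField(
    "cyp2c19_variant_status", FieldKind.GERMLINE_VARIANT_STATUS, FieldSource.LABORATORY_DB, "CYP2C19"
)
_CYP2D6_STATUS = ClinicalDataField(
    "cyp2d6_variant_status", FieldKind.GERMLINE_VARIANT_STATUS, FieldSource.LABORATORY_DB, "CYP2D6"
)
_SK_CYP2C9_PM = ClinicalDataField(
    "sk_cyp2c9_poor_metabolism",
    FieldKind.DERIVED_PHENOTYPE_CLASS,
    FieldSource.SUPPORTING_KNOWLEDGE,
    "CYP2C9 variants causing poor metabolism",
)
_SK_CYP2C19_PM = ClinicalDataField(
    "sk_cyp2c19_poor_metabolism",
    FieldKind.DERIVED_PHENOTYPE_CLASS,
    FieldSource.SUPPORTING_KNOWLEDGE,
    "CYP2C19 variants causing poor metabolism",
)
_SK_CYP2D6_PM = ClinicalDataField(
    "sk_cyp2d6_poor_metabolism",
    FieldKind.DERIVED_PHENOTYPE_CLASS,
    FieldSource.SUPPORTING_KNOWLEDGE,
    "CYP2D6 variants causing poor metabolism",
)
_SK_CYP2D6_INHIBITORS = ClinicalDataField(
    "sk_cyp2d6_inhibitors",
    FieldKind.DERIVED_PHENOTYPE_CLASS,
    FieldSource.SUPPORTING_KNOWLEDGE,
    "Medications that are CYP2D6 inhibitors",
)
_SK_CYP2D6_SUBSTRATES = ClinicalDataField(
    "sk_cyp2d6_substrates",
    FieldKind.DERIVED_PHENOTYPE_CLASS,
    FieldSource.SUPPORTING_KNOWLEDGE,
    "Medications metabolized by CYP2D6",
)


def _med_field(field_id: str, detail: str) -> ClinicalDataField:
    return ClinicalDataField(field_id, FieldKind.MEDICATION, FieldSource.INPATIENT_OUTPATIENT_DB, detail)


def _imatinib_rule() -> PGxRule:
    return PGxRule(
        rule_id="imatinib-ckit-asm-dose",
        drug="Imatinib mesylate",
        biomarker="c-Kit",
        antecedent=And(
            (
                Condition.make(
                    Predicate.MEDICATION_ACTIVE,
                    {"drug": "imatinib mesylate"},
                    _med_field("med_imatinib", "Imatinib mesylate (Gleevec)"),
                ),
                Condition.make(
                    Predicate.HAS_DISEASE,
                    {"disease": "ASM"},
                    ClinicalDataField(
                        "disease_asm_dfsp_gist",
                        FieldKind.DISEASE_STATUS,
                        FieldSource.INPATIENT_OUTPATIENT_DB,
                        "ASM, DFSP, or GIST",
                    ),
                ),
                Condition.make(
                    Predicate.TUMOR_HAS_MUTATION,
                    {"mutation": "c-kit d816v"},
                    ClinicalDataField(
                        "tumor_ckit_genotype",
                        FieldKind.TUMOR_PATHOGEN_GENOTYPE,
                        FieldSource.LABORATORY_DB,
                        "gastrointestinal stromal tumor c-Kit expression",
                    ),
                ),
            )
        ),
        consequents=[
            ThenStatement("recommended dose of Gleevec is 400 mg/day", ActionSpecificity.CLEAR, False)
        ],
        general_category=SupportCategory.DOSE_ADJUSTMENT,
        provenance="Dosage and Administration",
    )


def _celecoxib_rule() -> PGxRule:
    return PGxRule(
        rule_id="celecoxib-cyp2c9-pm-dose",
        drug="Celecoxib",
        biomarker="CYP2C9",
        antecedent=And(
            (
                Condition.make(
                    Predicate.MEDICATION_ACTIVE, {"drug": "celecoxib"}, _med_field("med_celecoxib", "Celecoxib")
                ),
                Condition.make(Predicate.HAS_VARIANT, {"gene": "CYP2C9"}, _CYP2C9_STATUS),
                Condition.make(
                    Predicate.HAS_PHENOTYPE_CLASS,
                    {"gene": "CYP2C9", "phenotype_class": "poor_metabolizer"},
                    _CYP2C9_STATUS,
                    sk_requirement=_SK_CYP2C9_PM,
                ),
            )
        ),
        consequents=[
            ThenStatement("the dose of Celecoxib should be reduced by 50%", ActionSpecificity.CLEAR, False)
        ],
        general_category=SupportCategory.DOSE_ADJUSTMENT,
        provenance="Dosage and Administration",
    )


def _clopidogrel_rule() -> PGxRule:
    return PGxRule(
        rule_id="clopidogrel-cyp2c19-pm-dose",
        drug="Clopidogrel",
        biomarker="CYP2C19",
        antecedent=And(
            (
                Condition.make(
                    Predicate.MEDICATION_ACTIVE,
                    {"drug": "clopidogrel"},
                    _med_field("med_clopidogrel", "Clopidogrel (Plavix)"),
                ),
                Condition.make(Predicate.HAS_VARIANT, {"gene": "CYP2C19"}, _CYP2C19_STATUS),
                Condition.make(
                    Predicate.HAS_PHENOTYPE_CLASS,
                    {"gene": "CYP2C19", "phenotype_class": "poor_metabolizer"},
                    _CYP2C19_STATUS,
                    sk_requirement=_SK_CYP2C19_PM,
                ),
            )
        ),
        consequents=[
            ThenStatement(
                "the dose adjustment for Clopidogrel is unknown for the patient",
                ActionSpecificity.NONE,
                False,
            )
        ],
        general_category=SupportCategory.DOSE_ADJUSTMENT,
        provenance="Clinical Pharmacology",
    )


def _atomoxetine_rule() -> PGxRule:
    return PGxRule(
        rule_id="atomoxetine-cyp2d6-dose",
        drug="Atomoxetine",
        biomarker="CYP2D6",
        antecedent=And(
            (
                Condition.make(
                    Predicate.MEDICATION_ACTIVE, {"drug": "atomoxetine"}, _med_field("med_atomoxetine", "Atomoxetine")
                ),
                Or(
                    (
                        Condition.make(
                            Predicate.HAS_DISEASE,
                            {"disease": "hepatic impairment"},
                            ClinicalDataField(
                                "disease_hepatic_impairment",
                                FieldKind.DISEASE_STATUS,
                                FieldSource.INPATIENT_OUTPATIENT_DB,
                                "hepatic impairment",
                            ),
                        ),
                        Condition.make(
                            Predicate.TAKING_DRUG_IN_CLASS,
                            {"drug_class": "strong_cyp2d6_inhibitors"},
                            _MEDICATION_LIST,
                            sk_requirement=_SK_CYP2D6_INHIBITORS,
                        ),
                        Condition.make(
                            Predicate.HAS_PHENOTYPE_CLASS,
                            {"gene": "CYP2D6", "phenotype_class": "poor_metabolizer"},
                            _CYP2D6_STATUS,
                            sk_requirement=_SK_CYP2D6_PM,
                        ),
                    )
                ),
            )
        ),
        consequents=[
            ThenStatement("the dose of Atomoxetine should be adjusted", ActionSpecificity.VAGUE, False)
        ],
        general_category=SupportCategory.DOSE_ADJUSTMENT,
        provenance="Dosage and Administration",
    )


def _fluoxetine_rule() -> PGxRule:
    return PGxRule(
        rule_id="fluoxetine-cyp2d6-coadministration",
        drug="Fluoxetine HCL",
        biomarker="CYP2D6",
        antecedent=And(
            (
                Condition.make(
                    Predicate.MEDICATION_CONSIDERED,
                    {"drug": "fluoxetine hcl"},
                    _med_field("med_fluoxetine", "Fluoxetine HCL (Prozac)"),
                ),
                Condition.make(
                    Predicate.TAKING_DRUG_IN_CLASS,
                    {"drug_class": "cyp2d6_substrates"},
                    _MEDICATION_LIST,
                    sk_requirement=_SK_CYP2D6_SUBSTRATES,
                ),
            )
        ),
        consequents=[
            ThenStatement(
                "coadministration should be approached with caution", ActionSpecificity.VAGUE, True
            )
        ],
        general_category=SupportCategory.COADMINISTRATION,
        provenance="Warnings and Precautions",
    )


def table2_rules() -> RuleCatalog:
    """The five worked example rules, in printed order."""
    return RuleCatalog(
        rules=[
            _imatinib_rule(),
            _celecoxib_rule(),
            _clopidogrel_rule(),
            _atomoxetine_rule(),
            _fluoxetine_rule(),
        ],
        metadata={"name": "worked-example-rules", "version": "1"},
    )


def warfarin_rule() -> PGxRule:
    """IF on warfarin AND carrying CYP2C9 *2 or *3 THEN reduced S-warfarin
    clearance AND increased bleeding risk."""
    return PGxRule(
        rule_id="warfarin-cyp2c9-bleeding-risk",
        drug="Warfarin",
        biomarker="CYP2C9",
        antecedent=And(
            (
                Condition.make(
                    Predicate.MEDICATION_ACTIVE, {"drug": "warfarin"}, _med_field("med_warfarin", "Warfarin")
                ),
                Or(
                    (
                        Condition.make(Predicate.HAS_VARIANT, {"gene": "CYP2C9", "allele": "*2"}, _CYP2C9_STATUS),
                        Condition.make(Predicate.HAS_VARIANT, {"gene": "CYP2C9", "allele": "*3"}, _CYP2C9_STATUS),
                    )
                ),
            )
        ),
        consequents=[
            ThenStatement("there will be a decrease in S-warfarin clearance", ActionSpecificity.NONE, False),
            ThenStatement("there is an increased bleeding risk", ActionSpecificity.NONE, True),
        ],
        general_category=SupportCategory.PRE_TREATMENT_CONSIDERATION,
        provenance="Clinical Pharmacology",
    )


def table1_matrix() -> KnowledgeMatrix:
    """The 28-drug encoded-knowledge matrix.

    Drugs holding at least one structured knowledge form are tagged
    ENCODED; availability-class tags beyond that are left to callers.
    """
    matrix = KnowledgeMatrix.from_tsv(data_path("table1_matrix.tsv").read_text())
    matrix.classes = {
        drug: (frozenset({AvailabilityClass.ENCODED}) if forms else frozenset())
        for drug, forms in matrix.forms.items()
    }
    return matrix
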
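"""Patient-level rule evaluation under Kleene (strong) three-valued logic.

Clinical records are chronically incomplete: a missing genotype is not a
negative genotype.  Conditions therefore evaluate to TRUE, FALSE, or
UNKNOWN, combined with Kleene connectives (FALSE dominates AND, TRUE
dominates OR, NOT preserves UNKNOWN).  A rule fires only when its
antecedent is definitely TRUE; an UNKNOWN antecedent yields an
INDETERMINATE status that lists exactly which clinical-data fields block
the decision — the signal the coverage analysis consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

from .certainty_classifier import CertaintyLexicon, classify_rule
from .errors import CatalogFormatError, EmptyCatalogError, UnitMismatchError
from .knowledge_engine import (
    F_AGE,
    F_DEMOGRAPHIC_CLASS,
    F_DISEASE,
    F_GENOTYPE,
    F_IN_DRUG_CLASS,
    F_LAB,
    F_MED_ACTIVE,
    F_MED_CONSIDERED,
    F_PHENOTYPE_CLASS,
    F_SEX,
    F_TUMOR_MUTATION,
    Fact,
    FactBase,
    SupportingKnowledgeRule,
    derive_facts,
)
from .rule_model import (
    And,
    ClinicalDataField,
    Condition,
    ConditionNode,
    Not,
    Or,
    PGxRule,
    Predicate,
    PresentationType,
    RuleCatalog,
    diplotype_has_allele,
    normalize_diplotype,
    normalize_drug,
)


class TV(Enum):
    """Three-valued truth value."""

    TRUE = "TRUE"
    FALSE = "FALSE"
    UNKNOWN = "UNKNOWN"


def kleene_and(values: Iterable[TV]) -> TV:
    out = TV.TRUE
    for v in values:
        if v is TV.FALSE:
            return TV.FALSE
        if v is TV.UNKNOWN:
            out = TV.UNKNOWN
    return out


def kleene_or(values: Iterable[TV]) -> TV:
    out = TV.FALSE
    for v in values:
        if v is TV.TRUE:
            return TV.TRUE
        if v is TV.UNKNOWN:
            out = TV.UNKNOWN
    return out


def kleene_not(v: TV) -> TV:
    if v is TV.TRUE:
        return TV.FALSE
    if v is TV.FALSE:
        return TV.TRUE
    return TV.UNKNOWN


# ---------------------------------------------------------------------------
# patient record


@dataclass
class PatientRecord:
    """The clinical facts a rule is evaluated against.

    ``None`` in an optional field means the record carries no data of that
    kind at all (distinct from an empty set, which is a definite negative).
    """

    patient_id: str
    age: float | None = None
    sex: str | None = None
    medications_active: set[str] | None = None
    medications_considered: set[str] | None = None
    disease_statuses: set[str] | None = None
    germline_genotypes: dict[str, str] | None = None  # gene -> diplotype "*a/*b"
    tumor_genotypes: set[str] | None = None
    lab_values: dict[str, tuple[float, str]] | None = None  # analyte -> (value, units)

    def __post_init__(self) -> None:
        if self.age is not None and self.age < 0:
            raise ValueError("age must be non-negative")
        if self.medications_active is not None:
            self.medications_active = {normalize_drug(d) for d in self.medications_active}
        if self.medications_considered is not None:
            self.medications_considered = {normalize_drug(d) for d in self.medications_considered}
        if self.disease_statuses is not None:
            self.disease_statuses = {d.strip().lower() for d in self.disease_statuses}
        if self.germline_genotypes is not None:
            self.germline_genotypes = {
                g.strip().upper(): normalize_diplotype(d) for g, d in self.germline_genotypes.items()
            }
        if self.tumor_genotypes is not None:
            self.tumor_genotypes = {m.strip().lower() for m in self.tumor_genotypes}

    def to_facts(self) -> FactBase:
        fb = FactBase()
        if self.age is not None:
            fb.add(Fact(F_AGE, (self.age,)))
        if self.sex is not None:
            fb.add(Fact(F_SEX, (self.sex,)))
        for d in self.medications_active or ():
            fb.add(Fact(F_MED_ACTIVE, (d,)))
        for d in self.medications_considered or ():
            fb.add(Fact(F_MED_CONSIDERED, (d,)))
        for d in self.disease_statuses or ():
            fb.add(Fact(F_DISEASE, (d,)))
        for gene, dip in (self.germline_genotypes or {}).items():
            fb.add(Fact(F_GENOTYPE, (gene, dip)))
        for m in self.tumor_genotypes or ():
            fb.add(Fact(F_TUMOR_MUTATION, (m,)))
        for analyte, (value, units) in (self.lab_values or {}).items():
            fb.add(Fact(F_LAB, (analyte, value, units)))
        return fb

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PatientRecord":
        if "patient_id" not in d:
            raise CatalogFormatError("patient record missing patient_id", context="<patient>")
        known = {
            "patient_id",
            "age",
            "sex",
            "medications_active",
            "medications_considered",
            "disease_statuses",
            "germline_genotypes",
            "tumor_genotypes",
            "lab_values",
        }
        unknown = set(d) - known
        if unknown:
            raise CatalogFormatError(
                f"unknown patient-record key(s): {sorted(unknown)}", context=str(d["patient_id"])
            )
        labs = d.get("lab_values")
        try:
            return cls(
                patient_id=str(d["patient_id"]),
                age=d.get("age"),
                sex=d.get("sex"),
                medications_active=set(d["medications_active"]) if d.get("medications_active") is not None else None,
                medications_considered=(
                    set(d["medications_considered"]) if d.get("medications_considered") is not None else None
                ),
                disease_statuses=set(d["disease_statuses"]) if d.get("disease_statuses") is not None else None,
                germline_genotypes=dict(d["germline_genotypes"]) if d.get("germline_genotypes") is not None else None,
                tumor_genotypes=set(d["tumor_genotypes"]) if d.get("tumor_genotypes") is not None else None,
                lab_values={k: (float(v[0]), str(v[1])) for k, v in labs.items()} if labs is not None else None,
            )
        except (TypeError, ValueError) as exc:
            raise CatalogFormatError(f"malformed patient record: {exc}", context=str(d["patient_id"])) from exc

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"patient_id": self.patient_id}
        if self.age is not None:
            out["age"] = self.age
        if self.sex is not None:
            out["sex"] = self.sex
        for key in ("medications_active", "medications_considered", "disease_statuses", "tumor_genotypes"):
            val = getattr(self, key)
            if val is not None:
                out[key] = sorted(val)
        if self.germline_genotypes is not None:
            out["germline_genotypes"] = dict(sorted(self.germline_genotypes.items()))
        if self.lab_values is not None:
            out["lab_values"] = {k: [v, u] for k, (v, u) in sorted(self.lab_values.items())}
        return out


def load_patient(path: str | Path) -> PatientRecord:
    return PatientRecord.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# condition evaluation


_COMPARE = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    "=": lambda a, b: a == b,
    ">=": lambda a, b: a >= b,
    ">": lambda a, b: a > b,
}


def eval_condition(cond: Condition, patient: PatientRecord, facts: FactBase) -> TV:
    """Evaluate one leaf condition to TRUE / FALSE / UNKNOWN.

    UNKNOWN means the record has no data for the referenced field (e.g. the
    gene is absent from ``germline_genotypes``); data that is present but
    unsatisfying is FALSE.
    """
    args = cond.argmap
    p = cond.predicate

    if p in (Predicate.MEDICATION_ACTIVE, Predicate.MEDICATION_CONSIDERED):
        meds = patient.medications_active if p is Predicate.MEDICATION_ACTIVE else patient.medications_considered
        if meds is None:
            return TV.UNKNOWN
        return TV.TRUE if normalize_drug(str(args["drug"])) in meds else TV.FALSE

    if p is Predicate.TAKING_DRUG_IN_CLASS:
        if Fact(F_IN_DRUG_CLASS, (args["drug_class"],)) in facts:
            return TV.TRUE
        return TV.UNKNOWN if patient.medications_active is None else TV.FALSE

    if p is Predicate.HAS_DISEASE:
        if patient.disease_statuses is None:
            return TV.UNKNOWN
        return TV.TRUE if str(args["disease"]).strip().lower() in patient.disease_statuses else TV.FALSE

    if p is Predicate.HAS_VARIANT:
        gene = str(args["gene"]).strip().upper()
        genotypes = patient.germline_genotypes
        if genotypes is None or gene not in genotypes:
            return TV.UNKNOWN
        dip = genotypes[gene]
        if "diplotype" in args:
            return TV.TRUE if dip == normalize_diplotype(str(args["diplotype"])) else TV.FALSE
        if "allele" in args and args["allele"]:
            return TV.TRUE if diplotype_has_allele(dip, str(args["allele"])) else TV.FALSE
        # no allele named: any variant (non-*1) allele counts
        return TV.TRUE if any(a != "*1" for a in dip.split("/")) else TV.FALSE

    if p is Predicate.HAS_PHENOTYPE_CLASS:
        gene = str(args["gene"]).strip().upper()
        if Fact(F_PHENOTYPE_CLASS, (gene, args["phenotype_class"])) in facts:
            return TV.TRUE
        # class facts also derive from non-genotype sources (e.g. age -> child)
        if Fact(F_DEMOGRAPHIC_CLASS, (args["phenotype_class"],)) in facts:
            return TV.TRUE
        if patient.germline_genotypes is not None and gene in patient.germline_genotypes:
            return TV.FALSE
        return TV.UNKNOWN

    if p is Predicate.TUMOR_HAS_MUTATION:
        if patient.tumor_genotypes is None:
            return TV.UNKNOWN
        return TV.TRUE if str(args["mutation"]).strip().lower() in patient.tumor_genotypes else TV.FALSE

    if p is Predicate.AGE_COMPARE:
        if patient.age is None:
            return TV.UNKNOWN
        return TV.TRUE if _COMPARE[args["comparator"]](patient.age, args["threshold"]) else TV.FALSE

    if p is Predicate.LAB_COMPARE:
        labs = patient.lab_values
        analyte = str(args["analyte"])
        if labs is None or analyte not in labs:
            return TV.UNKNOWN
        value, units = labs[analyte]
        if units != args["units"]:
            raise UnitMismatchError(
                f"lab {analyte!r}: record has units {units!r}, condition expects {args['units']!r}"
            )
        return TV.TRUE if _COMPARE[args["comparator"]](value, args["threshold"]) else TV.FALSE

    raise ValueError(f"unhandled predicate {p}")  # pragma: no cover


def _eval_tree(
    node: ConditionNode,
    patient: PatientRecord,
    facts: FactBase,
    unknown_fields: set[ClinicalDataField],
) -> TV:
    if isinstance(node, Condition):
        v = eval_condition(node, patient, facts)
        if v is TV.UNKNOWN:
            unknown_fields.add(node.field)
            if node.sk_requirement is not None:
                unknown_fields.add(node.sk_requirement)
        return v
    if isinstance(node, And):
        return kleene_and(_eval_tree(c, patient, facts, unknown_fields) for c in node.children)
    if isinstance(node, Or):
        return kleene_or(_eval_tree(c, patient, facts, unknown_fields) for c in node.children)
    if isinstance(node, Not):
        return kleene_not(_eval_tree(node.child, patient, facts, unknown_fields))
    raise TypeError(f"not a condition node: {node!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# rule and catalog evaluation


class Status(str, Enum):
    FIRED = "FIRED"
    NOT_FIRED = "NOT_FIRED"
    INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True)
class EvalStatus:
    value: Status
    missing_fields: frozenset[ClinicalDataField] = frozenset()


@dataclass(frozen=True)
class Alert:
    rule_id: str
    presentation_type: PresentationType
    message: str
    matched_conditions: tuple[tuple[Condition, TV], ...] = ()

    def render(self) -> str:
        return f"[{self.presentation_type.value}] {self.rule_id}: {self.message}"


def evaluate_rule(
    rule: PGxRule,
    patient: PatientRecord,
    sk_rules: Sequence[SupportingKnowledgeRule] = (),
    lexicon: CertaintyLexicon | None = None,
) -> tuple[EvalStatus, Alert | None]:
    """Evaluate one rule: derive supporting facts, then the antecedent.

    Returns the status and, when the rule fires, a typed alert combining
    all consequent statements.  A rule never fires on UNKNOWN; the
    INDETERMINATE status lists the fields whose absence blocked it.
    """
    facts = derive_facts(patient.to_facts(), sk_rules)
    unknown_fields: set[ClinicalDataField] = set()
    value = _eval_tree(rule.antecedent, patient, facts, unknown_fields)
    if value is TV.TRUE:
        ptype = rule.presentation_type or classify_rule(rule, lexicon)
        matched = tuple(
            (c, eval_condition(c, patient, facts))
            for c in _true_leaves(rule.antecedent, patient, facts)
        )
        message = " AND ".join(s.text for s in rule.consequents)
        return EvalStatus(Status.FIRED), Alert(rule.rule_id, ptype, message, matched)
    if value is TV.UNKNOWN:
        return EvalStatus(Status.INDETERMINATE, frozenset(unknown_fields)), None
    return EvalStatus(Status.NOT_FIRED), None


def _true_leaves(node: ConditionNode, patient: PatientRecord, facts: FactBase) -> list[Condition]:
    from .rule_model import leaves

    return [c for c in leaves(node) if eval_condition(c, patient, facts) is TV.TRUE]


@dataclass
class CatalogEvaluation:
    statuses: dict[str, EvalStatus]
    alerts: list[Alert]

    def to_jsonl(self) -> str:
        lines = []
        for a in self.alerts:
            lines.append(
                json.dumps(
                    {"rule_id": a.rule_id, "presentation_type": a.presentation_type.value, "message": a.message},
                    sort_keys=True,
                )
            )
        return "\n".join(lines) + ("\n" if lines else "")

    def render(self) -> str:
        out = [a.render() for a in self.alerts]
        out.append("")
        for rule_id in sorted(self.statuses):
            st = self.statuses[rule_id]
            line = f"{rule_id}: {st.value.value}"
            if st.missing_fields:
                line += " (missing: " + ", ".join(sorted(f.field_id for f in st.missing_fields)) + ")"
            out.append(line)
        return "\n".join(out) + "\n"


def evaluate_catalog(
    catalog: RuleCatalog,
    patient: PatientRecord,
    sk_rules: Sequence[SupportingKnowledgeRule] = (),
    lexicon: CertaintyLexicon | None = None,
) -> CatalogEvaluation:
    """Evaluate every rule; alerts sorted severity-first, then rule_id."""
    if not catalog.rules:
        raise EmptyCatalogError("cannot evaluate an empty catalog")
    statuses: dict[str, EvalStatus] = {}
    alerts: list[Alert] = []
    for rule in catalog.rules:
        status, alert = evaluate_rule(rule, patient, sk_rules, lexicon)
        statuses[rule.rule_id] = status
        if alert is not None:
            alerts.append(alert)
    alerts.sort(key=lambda a: (-a.presentation_type.severity, a.rule_id))
    return CatalogEvaluation(statuses=statuses, alerts=alerts)
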
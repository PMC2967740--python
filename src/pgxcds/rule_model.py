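"""Domain model for pharmacogenomic (PGx) decision-support rules.

A :class:`PGxRule` captures one actionable drug-label statement as an
if-then rule: an antecedent condition tree over clinical data (medications,
diseases, germline star-allele genotypes, tumor/pathogen genotypes,
demographics, labs, and derived phenotype classes) and one or more
consequent statements.  Rules live in a :class:`RuleCatalog` with a
versioned YAML/JSON interchange format.

Structural problems are reported as :class:`Violation` values from
:func:`validate_rule` / :func:`validate_catalog` rather than raised, so a
curation workflow can collect them all in one pass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from enum import Enum
from pathlib import Path
from typing import Any, Iterator, Mapping, Union

import yaml

from .errors import CatalogFormatError, InvalidRuleError

FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# enumerations


class FieldKind(str, Enum):
    MEDICATION = "MEDICATION"
    MEDICATION_LIST = "MEDICATION_LIST"
    DISEASE_STATUS = "DISEASE_STATUS"
    GERMLINE_VARIANT_STATUS = "GERMLINE_VARIANT_STATUS"
    TUMOR_PATHOGEN_GENOTYPE = "TUMOR_PATHOGEN_GENOTYPE"
    DEMOGRAPHIC = "DEMOGRAPHIC"
    LAB_VALUE = "LAB_VALUE"
    DERIVED_PHENOTYPE_CLASS = "DERIVED_PHENOTYPE_CLASS"


class FieldSource(str, Enum):
    INPATIENT_OUTPATIENT_DB = "INPATIENT_OUTPATIENT_DB"
    LABORATORY_DB = "LABORATORY_DB"
    SUPPORTING_KNOWLEDGE = "SUPPORTING_KNOWLEDGE"


class Predicate(str, Enum):
    MEDICATION_ACTIVE = "MEDICATION_ACTIVE"
    MEDICATION_CONSIDERED = "MEDICATION_CONSIDERED"
    TAKING_DRUG_IN_CLASS = "TAKING_DRUG_IN_CLASS"
    HAS_DISEASE = "HAS_DISEASE"
    HAS_VARIANT = "HAS_VARIANT"
    HAS_PHENOTYPE_CLASS = "HAS_PHENOTYPE_CLASS"
    TUMOR_HAS_MUTATION = "TUMOR_HAS_MUTATION"
    AGE_COMPARE = "AGE_COMPARE"
    LAB_COMPARE = "LAB_COMPARE"


class ActionSpecificity(str, Enum):
    NONE = "NONE"
    VAGUE = "VAGUE"
    CLEAR = "CLEAR"


class SupportCategory(str, Enum):
    """General category of decision support a rule provides."""

    DOSE_ADJUSTMENT = "DOSE_ADJUSTMENT"
    PATIENT_MONITORING = "PATIENT_MONITORING"
    PRE_TREATMENT_CONSIDERATION = "PRE_TREATMENT_CONSIDERATION"
    BENEFIT_PREDICTION = "BENEFIT_PREDICTION"
    TESTING_GUIDANCE = "TESTING_GUIDANCE"
    COADMINISTRATION = "COADMINISTRATION"
    PATIENT_COMMUNICATION = "PATIENT_COMMUNICATION"


class PresentationType(str, Enum):
    """How actionable an alert is; severity orders WARNING > RECOMMENDATION > INFORMATION."""

    INFORMATION = "INFORMATION"
    RECOMMENDATION = "RECOMMENDATION"
    WARNING = "WARNING"

    @property
    def severity(self) -> int:
        return _SEVERITY[self]


_SEVERITY = {
    PresentationType.INFORMATION: 0,
    PresentationType.RECOMMENDATION: 1,
    PresentationType.WARNING: 2,
}

COMPARATORS = ("<", "<=", "=", ">=", ">")


# ---------------------------------------------------------------------------
# normalization helpers


def normalize_drug(name: str) -> str:
    """Lowercase, whitespace-collapsed generic drug name."""
    return " ".join(name.strip().lower().split())


_ALLELE_RE = re.compile(r"\*(\d+)([A-Za-z0-9]*)")


def _allele_key(allele: str) -> tuple[int, str]:
    m = _ALLELE_RE.fullmatch(allele.strip())
    if not m:
        return (10**9, allele.strip())
    return (int(m.group(1)), m.group(2))


def normalize_diplotype(diplotype: str) -> str:
    """Normalize a star-allele diplotype to ``*a/*b`` with alleles ascending.

    Accepts an optional gene prefix (``CYP2C9*3/*2`` -> ``*2/*3``); ordering
    is numeric on the star number with any suffix breaking ties.
    """
    s = diplotype.strip()
    star = s.find("*")
    if star < 0:
        raise ValueError(f"not a star-allele diplotype: {diplotype!r}")
    s = s[star:]
    parts = [p if p.startswith("*") else "*" + p for p in (q.strip() for q in s.split("/"))]
    if len(parts) != 2:
        raise ValueError(f"diplotype must have two alleles: {diplotype!r}")
    a, b = sorted(parts, key=_allele_key)
    return f"{a}/{b}"


def diplotype_alleles(diplotype: str) -> tuple[str, str]:
    a, b = normalize_diplotype(diplotype).split("/")
    return a, b


def diplotype_has_allele(diplotype: str, allele: str) -> bool:
    """True if either chromosome carries ``allele`` (e.g. ``*2`` in ``*1/*2``)."""
    want = allele.strip()
    if not want.startswith("*"):
        want = "*" + want
    return want in diplotype_alleles(diplotype)


class DrugSynonyms:
    """Alias -> canonical generic-name table (brand names like Plavix -> clopidogrel)."""

    def __init__(self, mapping: Mapping[str, str] | None = None):
        self._map = {normalize_drug(k): normalize_drug(v) for k, v in (mapping or {}).items()}

    def canonical(self, name: str) -> str:
        n = normalize_drug(name)
        return self._map.get(n, n)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DrugSynonyms":
        mapping: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            alias, canonical = line.split("\t")[:2]
            mapping[alias] = canonical
        return cls(mapping)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ClinicalDataField:
    """One type of clinical data a condition reads, tagged with where it lives."""

    field_id: str
    kind: FieldKind
    source: FieldSource
    detail: str = ""


@dataclass(frozen=True)
class Condition:
    """A typed leaf predicate over one clinical-data field.

    ``args`` is a predicate-specific mapping (stored as a sorted tuple of
    pairs so conditions are hashable).  ``sk_requirement`` names the piece of
    supporting knowledge (phenotype-class definition or drug-class
    membership) the predicate depends on, when any.
    """

    predicate: Predicate
    args: tuple[tuple[str, Any], ...]
    field: ClinicalDataField
    sk_requirement: ClinicalDataField | None = None

    @classmethod
    def make(
        cls,
        predicate: Predicate,
        args: Mapping[str, Any],
        field: ClinicalDataField,
        sk_requirement: ClinicalDataField | None = None,
    ) -> "Condition":
        return cls(predicate, tuple(sorted(args.items())), field, sk_requirement)

    @property
    def argmap(self) -> dict[str, Any]:
        return dict(self.args)


@dataclass(frozen=True)
class And:
    children: tuple["ConditionNode", ...]


@dataclass(frozen=True)
class Or:
    children: tuple["ConditionNode", ...]


@dataclass(frozen=True)
class Not:
    child: "ConditionNode"


ConditionNode = Union[Condition, And, Or, Not]


def all_of(*children: ConditionNode) -> And:
    return And(tuple(children))


def any_of(*children: ConditionNode) -> Or:
    return Or(tuple(children))


def leaves(node: ConditionNode) -> Iterator[Condition]:
    """Yield every leaf Condition in depth-first order."""
    if isinstance(node, Condition):
        yield node
    elif isinstance(node, (And, Or)):
        for child in node.children:
            yield from leaves(child)
    elif isinstance(node, Not):
        yield from leaves(node.child)
    else:  # pragma: no cover - defensive
        raise TypeError(f"not a condition node: {node!r}")


@dataclass(frozen=True)
class ThenStatement:
    """One consequent sentence with its curator annotations."""

    text: str
    action_specificity: ActionSpecificity
    consequence_flag: bool


@dataclass
class PGxRule:
    rule_id: str
    drug: str
    biomarker: str
    antecedent: ConditionNode
    consequents: list[ThenStatement]
    general_category: SupportCategory | None = None
    presentation_type: PresentationType | None = None
    provenance: str = ""


@dataclass
class RuleCatalog:
    rules: list[PGxRule]
    metadata: dict[str, Any] = dc_field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self) -> Iterator[PGxRule]:
        return iter(self.rules)


# ---------------------------------------------------------------------------
# validation

# required argument keys per predicate; values are checked further below
_ARG_SPEC: dict[Predicate, tuple[str, ...]] = {
    Predicate.MEDICATION_ACTIVE: ("drug",),
    Predicate.MEDICATION_CONSIDERED: ("drug",),
    Predicate.TAKING_DRUG_IN_CLASS: ("drug_class",),
    Predicate.HAS_DISEASE: ("disease",),
    Predicate.HAS_VARIANT: ("gene",),  # plus optional allele or diplotype
    Predicate.HAS_PHENOTYPE_CLASS: ("gene", "phenotype_class"),
    Predicate.TUMOR_HAS_MUTATION: ("mutation",),
    Predicate.AGE_COMPARE: ("comparator", "threshold"),
    Predicate.LAB_COMPARE: ("analyte", "comparator", "threshold", "units"),
}

_COMPARATOR_PREDICATES = {Predicate.AGE_COMPARE, Predicate.LAB_COMPARE}


@dataclass(frozen=True)
class Violation:
    code: str
    message: str
    path: str = ""


def _check_condition(cond: Condition, path: str, out: list[Violation]) -> None:
    args = cond.argmap
    spec = _ARG_SPEC[cond.predicate]
    missing = [k for k in spec if k not in args or args[k] in (None, "")]
    if missing:
        out.append(
            Violation(
                "INCOMPLETE_PREDICATE_ARGS",
                f"{cond.predicate.value} missing argument(s) {missing}",
                path,
            )
        )
    if cond.predicate in _COMPARATOR_PREDICATES and "comparator" in args:
        if args["comparator"] not in COMPARATORS:
            out.append(
                Violation("BAD_COMPARATOR", f"comparator {args['comparator']!r} not one of {COMPARATORS}", path)
            )
        thr = args.get("threshold")
        if thr is not None and not isinstance(thr, (int, float)):
            out.append(Violation("INCOMPLETE_PREDICATE_ARGS", "threshold must be numeric", path))
    if cond.predicate is Predicate.HAS_VARIANT and "allele" in args and "diplotype" in args:
        out.append(Violation("INCOMPLETE_PREDICATE_ARGS", "give allele or diplotype, not both", path))
    if not cond.field.field_id:
        out.append(Violation("MISSING_FIELD", "condition field has empty field_id", path))
    for f in filter(None, (cond.field, cond.sk_requirement)):
        if f.kind is FieldKind.DERIVED_PHENOTYPE_CLASS and f.source is not FieldSource.SUPPORTING_KNOWLEDGE:
            out.append(
                Violation(
                    "DERIVED_FIELD_SOURCE",
                    f"field {f.field_id!r}: DERIVED_PHENOTYPE_CLASS must come from SUPPORTING_KNOWLEDGE",
                    path,
                )
            )


def _check_tree(node: ConditionNode, path: str, out: list[Violation]) -> None:
    if isinstance(node, Condition):
        _check_condition(node, path, out)
    elif isinstance(node, (And, Or)):
        op = "and" if isinstance(node, And) else "or"
        if len(node.children) < 2:
            out.append(Violation("EMPTY_BOOLEAN_NODE", f"{op.upper()} node needs >=2 children", path))
        for i, child in enumerate(node.children):
            _check_tree(child, f"{path}/{op}[{i}]", out)
    elif isinstance(node, Not):
        _check_tree(node.child, f"{path}/not", out)
    else:
        out.append(Violation("BAD_NODE", f"unrecognized antecedent node {type(node).__name__}", path))


def validate_rule(rule: PGxRule) -> list[Violation]:
    """Return every invariant violation in ``rule`` (empty list = valid)."""
    out: list[Violation] = []
    root = rule.rule_id or "<rule>"
    if not rule.rule_id:
        out.append(Violation("EMPTY_RULE_ID", "rule_id must be non-empty", root))
    if not rule.drug:
        out.append(Violation("EMPTY_DRUG", "drug must be non-empty", root))
    if not rule.biomarker:
        out.append(Violation("EMPTY_BIOMARKER", "biomarker must be non-empty", root))
    if not rule.consequents:
        out.append(Violation("MISSING_CONSEQUENT", "rule needs at least one THEN statement", root))
    for i, stmt in enumerate(rule.consequents):
        if not stmt.text:
            out.append(Violation("EMPTY_STATEMENT_TEXT", "consequent text empty", f"{root}/then[{i}]"))
        if not isinstance(stmt.action_specificity, ActionSpecificity):
            out.append(Violation("MISSING_ANNOTATION", "action_specificity missing", f"{root}/then[{i}]"))
        if not isinstance(stmt.consequence_flag, bool):
            out.append(Violation("MISSING_ANNOTATION", "consequence_flag missing", f"{root}/then[{i}]"))
    _check_tree(rule.antecedent, f"{root}/if", out)
    if next(leaves(rule.antecedent), None) is None:
        out.append(Violation("NO_LEAF_CONDITION", "antecedent has no leaf condition", f"{root}/if"))
    return out


def validate_catalog(catalog: RuleCatalog) -> list[Violation]:
    """Per-rule violations plus catalog-level identity/uniqueness checks."""
    out: list[Violation] = []
    seen_ids: set[str] = set()
    field_defs: dict[str, ClinicalDataField] = {}
    for rule in catalog.rules:
        out.extend(validate_rule(rule))
        if rule.rule_id in seen_ids:
            out.append(Violation("DUPLICATE_RULE_ID", f"rule_id {rule.rule_id!r} repeated", rule.rule_id))
        seen_ids.add(rule.rule_id)
        for cond in leaves(rule.antecedent):
            for f in filter(None, (cond.field, cond.sk_requirement)):
                prev = field_defs.setdefault(f.field_id, f)
                if prev != f:
                    out.append(
                        Violation(
                            "FIELD_ID_CONFLICT",
                            f"field_id {f.field_id!r} bound to two different definitions",
                            rule.rule_id,
                        )
                    )
    return out


# ---------------------------------------------------------------------------
# requirement extraction


@dataclass(frozen=True)
class RequirementSet:
    """The clinical-data fields a rule needs, split raw vs supporting knowledge."""

    fields: frozenset[ClinicalDataField]
    sk_requirements: frozenset[ClinicalDataField]

    def by_source(self) -> dict[FieldSource, frozenset[ClinicalDataField]]:
        out: dict[FieldSource, set[ClinicalDataField]] = {s: set() for s in FieldSource}
        for f in self.fields:
            out[f.source].add(f)
        for f in self.sk_requirements:
            out[FieldSource.SUPPORTING_KNOWLEDGE].add(f)
        return {s: frozenset(v) for s, v in out.items()}

    @property
    def all_fields(self) -> frozenset[ClinicalDataField]:
        return self.fields | self.sk_requirements

    def sorted_fields(self) -> list[ClinicalDataField]:
        return sorted(self.all_fields, key=lambda f: f.field_id)


def antecedent_fields(rule: PGxRule) -> RequirementSet:
    """Union of fields referenced by all leaf conditions, set semantics.

    Invalid rules are rejected (the extraction would silently misreport an
    incomplete antecedent otherwise).
    """
    violations = validate_rule(rule)
    if violations:
        raise InvalidRuleError(
            f"rule {rule.rule_id!r} invalid: " + "; ".join(v.code for v in violations)
        )
    fields: set[ClinicalDataField] = set()
    sk: set[ClinicalDataField] = set()
    for cond in leaves(rule.antecedent):
        fields.add(cond.field)
        if cond.sk_requirement is not None:
            sk.add(cond.sk_requirement)
    return RequirementSet(frozenset(fields), frozenset(sk))


# ---------------------------------------------------------------------------
# interchange (YAML; JSON accepted on load since YAML is a superset)


def _field_to_dict(f: ClinicalDataField) -> dict[str, str]:
    return {"field_id": f.field_id, "kind": f.kind.value, "source": f.source.value, "detail": f.detail}


def _field_from_dict(d: Mapping[str, Any], ctx: str) -> ClinicalDataField:
    try:
        return ClinicalDataField(
            field_id=str(d["field_id"]),
            kind=FieldKind(d["kind"]),
            source=FieldSource(d["source"]),
            detail=str(d.get("detail", "")),
        )
    except (KeyError, ValueError) as exc:
        raise CatalogFormatError(f"bad clinical-data field: {exc}", context=ctx) from exc


def _node_to_dict(node: ConditionNode) -> dict[str, Any]:
    if isinstance(node, And):
        return {"and": [_node_to_dict(c) for c in node.children]}
    if isinstance(node, Or):
        return {"or": [_node_to_dict(c) for c in node.children]}
    if isinstance(node, Not):
        return {"not": _node_to_dict(node.child)}
    d: dict[str, Any] = {
        "predicate": node.predicate.value,
        "args": dict(node.args),
        "field": _field_to_dict(node.field),
    }
    if node.sk_requirement is not None:
        d["sk_requirement"] = _field_to_dict(node.sk_requirement)
    return d


def _node_from_dict(d: Mapping[str, Any], ctx: str) -> ConditionNode:
    if not isinstance(d, Mapping):
        raise CatalogFormatError("antecedent node must be a mapping", context=ctx)
    if "and" in d:
        return And(tuple(_node_from_dict(c, f"{ctx}/and[{i}]") for i, c in enumerate(d["and"])))
    if "or" in d:
        return Or(tuple(_node_from_dict(c, f"{ctx}/or[{i}]") for i, c in enumerate(d["or"])))
    if "not" in d:
        return Not(_node_from_dict(d["not"], f"{ctx}/not"))
    try:
        predicate = Predicate(d["predicate"])
    except (KeyError, ValueError) as exc:
        raise CatalogFormatError(f"bad predicate: {exc}", context=ctx) from exc
    args = d.get("args") or {}
    if not isinstance(args, Mapping):
        raise CatalogFormatError("condition args must be a mapping", context=ctx)
    if "field" not in d:
        raise CatalogFormatError("condition missing field", context=ctx)
    sk = d.get("sk_requirement")
    return Condition.make(
        predicate,
        dict(args),
        _field_from_dict(d["field"], f"{ctx}/field"),
        _field_from_dict(sk, f"{ctx}/sk_requirement") if sk is not None else None,
    )


def rule_to_dict(rule: PGxRule) -> dict[str, Any]:
    d: dict[str, Any] = {
        "rule_id": rule.rule_id,
        "drug": rule.drug,
        "biomarker": rule.biomarker,
        "antecedent": _node_to_dict(rule.antecedent),
        "consequents": [
            {
                "text": s.text,
                "action_specificity": s.action_specificity.value,
                "consequence_flag": s.consequence_flag,
            }
            for s in rule.consequents
        ],
        "general_category": rule.general_category.value if rule.general_category else None,
        "provenance": rule.provenance,
    }
    if rule.presentation_type is not None:
        d["presentation_type"] = rule.presentation_type.value
    return d


def rule_from_dict(d: Mapping[str, Any], ctx: str = "") -> PGxRule:
    ctx = ctx or str(d.get("rule_id", "<rule>"))
    for key in ("rule_id", "drug", "biomarker", "antecedent", "consequents"):
        if key not in d:
            raise CatalogFormatError(f"rule missing required key {key!r}", context=ctx)
    consequents = []
    for i, s in enumerate(d["consequents"]):
        try:
            consequents.append(
                ThenStatement(
                    text=str(s["text"]),
                    action_specificity=ActionSpecificity(s["action_specificity"]),
                    consequence_flag=bool(s["consequence_flag"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise CatalogFormatError(f"bad consequent: {exc}", context=f"{ctx}/then[{i}]") from exc
    cat = d.get("general_category")
    pres = d.get("presentation_type")
    try:
        general_category = SupportCategory(cat) if cat else None
        presentation = PresentationType(pres) if pres else None
    except ValueError as exc:
        raise CatalogFormatError(f"bad category/presentation: {exc}", context=ctx) from exc
    return PGxRule(
        rule_id=str(d["rule_id"]),
        drug=str(d["drug"]),
        biomarker=str(d["biomarker"]),
        antecedent=_node_from_dict(d["antecedent"], f"{ctx}/if"),
        consequents=consequents,
        general_category=general_category,
        presentation_type=presentation,
        provenance=str(d.get("provenance", "")),
    )


def catalog_to_dict(catalog: RuleCatalog) -> dict[str, Any]:
    return {
        "format_version": FORMAT_VERSION,
        "metadata": dict(catalog.metadata),
        "rules": [rule_to_dict(r) for r in catalog.rules],
    }


def catalog_from_dict(doc: Mapping[str, Any]) -> RuleCatalog:
    if not isinstance(doc, Mapping):
        raise CatalogFormatError("catalog document must be a mapping", context="<root>")
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise CatalogFormatError(
            f"unsupported format_version {version!r} (expected {FORMAT_VERSION})",
            code="UNSUPPORTED_FORMAT_VERSION",
            context="<root>",
        )
    rules = [rule_from_dict(rd, f"rules[{i}]") for i, rd in enumerate(doc.get("rules") or [])]
    seen: set[str] = set()
    for r in rules:
        if r.rule_id in seen:
            raise CatalogFormatError(
                f"duplicate rule_id {r.rule_id!r}", code="DUPLICATE_RULE_ID", context=r.rule_id
            )
        seen.add(r.rule_id)
    return RuleCatalog(rules=rules, metadata=dict(doc.get("metadata") or {}))


def dumps_catalog(catalog: RuleCatalog) -> str:
    return yaml.safe_dump(catalog_to_dict(catalog), sort_keys=False, allow_unicode=True)


def loads_catalog(text: str) -> RuleCatalog:
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise CatalogFormatError(f"unparseable catalog: {exc}", context="<root>") from exc
    return catalog_from_dict(doc)


def save_catalog(catalog: RuleCatalog, path: str | Path) -> None:
    Path(path).write_text(dumps_catalog(catalog))


def load_catalog(path: str | Path) -> RuleCatalog:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    return loads_catalog(p.read_text())
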
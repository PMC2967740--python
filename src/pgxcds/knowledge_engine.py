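"""Forward-chaining derivation of intermediate clinical facts.

Decision rules often reference classes a raw record does not carry
directly: "the patient is a poor metabolizer of CYP2C9", "the patient is a
child", "the patient is taking a CYP2D6 inhibitor".  Supporting-knowledge
rules bridge the gap: each is a datalog-style clause whose body is a
conjunction of fact patterns (with optional numeric or allele guards) and
whose head derives one new ground fact, e.g.::

    IF genotype(CYP2C9, "*2/*3")  THEN phenotype_class(CYP2C9, poor_metabolizer)
    IF age(?a), ?a < 18           THEN demographic_class(child)

Facts are ground and positive only — no negation, no retraction — so the
closure is a unique least fixpoint, reached monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import yaml

from .errors import CatalogFormatError, DerivationLimitError, UnboundDerivationError
from .rule_model import diplotype_has_allele, normalize_diplotype, normalize_drug

RAW = "RAW"
HARD_ITERATION_CAP = 10_000

# fact predicate names used across the package
F_AGE = "age"
F_SEX = "sex"
F_MED_ACTIVE = "medication_active"
F_MED_CONSIDERED = "medication_considered"
F_DISEASE = "has_disease"
F_GENOTYPE = "genotype"
F_TUMOR_MUTATION = "tumor_mutation"
F_LAB = "lab"
F_PHENOTYPE_CLASS = "phenotype_class"
F_DEMOGRAPHIC_CLASS = "demographic_class"
F_IN_DRUG_CLASS = "taking_drug_in_class"


@dataclass(frozen=True)
class Fact:
    """A ground, hashable atom: predicate plus constant arguments."""

    predicate: str
    args: tuple[Any, ...]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.predicate}({', '.join(map(str, self.args))})"


@dataclass(frozen=True)
class Var:
    name: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"?{self.name}"


@dataclass(frozen=True)
class Pattern:
    """A fact template; arguments may be constants or :class:`Var`."""

    predicate: str
    args: tuple[Any, ...]

    def variables(self) -> set[Var]:
        return {a for a in self.args if isinstance(a, Var)}


GUARD_OPS = ("<", "<=", "=", ">=", ">", "has_allele")


@dataclass(frozen=True)
class Guard:
    """Side condition on a bound variable: numeric comparison or allele test."""

    var: Var
    op: str
    value: Any

    def holds(self, binding: Mapping[Var, Any]) -> bool:
        x = binding[self.var]
        if self.op == "has_allele":
            return diplotype_has_allele(str(x), str(self.value))
        ops = {
            "<": lambda a, b: a < b,
            "<=": lambda a, b: a <= b,
            "=": lambda a, b: a == b,
            ">=": lambda a, b: a >= b,
            ">": lambda a, b: a > b,
        }
        return ops[self.op](x, self.value)


@dataclass(frozen=True)
class SupportingKnowledgeRule:
    """One derivation clause: premises + guards => derived fact template."""

    sk_id: str
    premises: tuple[Pattern, ...]
    guards: tuple[Guard, ...]
    derived: Pattern

    def validate(self) -> None:
        if not self.premises:
            raise UnboundDerivationError(f"{self.sk_id}: empty antecedent")
        bound: set[Var] = set()
        for p in self.premises:
            bound |= p.variables()
        unbound = self.derived.variables() - bound
        if unbound:
            raise UnboundDerivationError(
                f"{self.sk_id}: derived template has unbound variable(s) "
                + ", ".join(sorted(str(v) for v in unbound))
            )
        for g in self.guards:
            if g.var not in bound:
                raise UnboundDerivationError(f"{self.sk_id}: guard on unbound variable {g.var}")
            if g.op not in GUARD_OPS:
                raise UnboundDerivationError(f"{self.sk_id}: unknown guard op {g.op!r}")


@dataclass
class FactBase:
    """A set of ground facts with per-fact provenance (RAW or deriving sk_id)."""

    facts: set[Fact] = dc_field(default_factory=set)
    provenance: dict[Fact, str] = dc_field(default_factory=dict)

    @classmethod
    def from_facts(cls, facts: Iterable[Fact], origin: str = RAW) -> "FactBase":
        fb = cls()
        for f in facts:
            fb.add(f, origin)
        return fb

    def add(self, fact: Fact, origin: str = RAW) -> bool:
        if fact in self.facts:
            return False
        self.facts.add(fact)
        self.provenance[fact] = origin
        return True

    def copy(self) -> "FactBase":
        fb = FactBase()
        fb.facts = set(self.facts)
        fb.provenance = dict(self.provenance)
        return fb

    def __contains__(self, fact: Fact) -> bool:
        return fact in self.facts

    def __len__(self) -> int:
        return len(self.facts)


def _match(pattern: Pattern, fact: Fact, binding: dict[Var, Any]) -> dict[Var, Any] | None:
    if pattern.predicate != fact.predicate or len(pattern.args) != len(fact.args):
        return None
    out = dict(binding)
    for pa, fa in zip(pattern.args, fact.args):
        if isinstance(pa, Var):
            if pa in out and out[pa] != fa:
                return None
            out[pa] = fa
        elif pa != fa:
            return None
    return out


def _instantiate(template: Pattern, binding: Mapping[Var, Any]) -> Fact:
    return Fact(template.predicate, tuple(binding[a] if isinstance(a, Var) else a for a in template.args))


def _rule_conclusions(rule: SupportingKnowledgeRule, facts: Sequence[Fact]) -> set[Fact]:
    """All facts derivable from ``facts`` by one application of ``rule``."""
    bindings: list[dict[Var, Any]] = [{}]
    for premise in rule.premises:
        nxt: list[dict[Var, Any]] = []
        for b in bindings:
            for f in facts:
                extended = _match(premise, f, b)
                if extended is not None:
                    nxt.append(extended)
        bindings = nxt
        if not bindings:
            return set()
    out: set[Fact] = set()
    for b in bindings:
        if all(g.holds(b) for g in rule.guards):
            out.add(_instantiate(rule.derived, b))
    return out


def derive_facts(base: FactBase, sk_rules: Sequence[SupportingKnowledgeRule]) -> FactBase:
    """Least fixpoint of ``base`` under ``sk_rules``.

    Iterates full rounds until no rule produces a new fact; monotone
    (output is a superset of input) and independent of rule order.  A hard
    iteration cap guards against malformed rule sets.
    """
    for rule in sk_rules:
        rule.validate()
    closure = base.copy()
    for _ in range(HARD_ITERATION_CAP):
        snapshot = tuple(closure.facts)
        changed = False
        for rule in sk_rules:
            for fact in _rule_conclusions(rule, snapshot):
                if closure.add(fact, rule.sk_id):
                    changed = True
        if not changed:
            return closure
    raise DerivationLimitError(f"derivation did not converge within {HARD_ITERATION_CAP} rounds")


# ---------------------------------------------------------------------------
# interchange: same YAML family as rule catalogs, with a derived: block


def _parse_term(t: Any) -> Any:
    if isinstance(t, str) and t.startswith("?"):
        return Var(t[1:])
    return t


def _pattern_from_dict(d: Mapping[str, Any], ctx: str) -> Pattern:
    try:
        return Pattern(str(d["fact"]), tuple(_parse_term(a) for a in d["args"]))
    except (KeyError, TypeError) as exc:
        raise CatalogFormatError(f"bad fact pattern: {exc}", context=ctx) from exc


def sk_rules_from_dict(doc: Mapping[str, Any]) -> list[SupportingKnowledgeRule]:
    rules: list[SupportingKnowledgeRule] = []
    for i, rd in enumerate(doc.get("rules") or []):
        ctx = str(rd.get("sk_id", f"rules[{i}]"))
        premises: list[Pattern] = []
        guards: list[Guard] = []
        for j, item in enumerate(rd.get("if") or []):
            if "guard" in item:
                g = item["guard"]
                guards.append(Guard(Var(str(g["var"]).lstrip("?")), str(g["op"]), g.get("value")))
            else:
                premises.append(_pattern_from_dict(item, f"{ctx}/if[{j}]"))
        rule = SupportingKnowledgeRule(
            sk_id=str(rd.get("sk_id", f"sk-{i}")),
            premises=tuple(premises),
            guards=tuple(guards),
            derived=_pattern_from_dict(rd.get("derived") or {}, f"{ctx}/derived"),
        )
        rule.validate()
        rules.append(rule)
    return rules


def load_sk_rules(path: str | Path) -> list[SupportingKnowledgeRule]:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, Mapping):
        raise CatalogFormatError("supporting-knowledge file must be a mapping", context=str(path))
    return sk_rules_from_dict(doc)


def drug_class_rules_from_tsv(path: str | Path) -> list[SupportingKnowledgeRule]:
    """Compile a (class_id, drug) membership TSV into per-drug derivation rules.

    Each member drug yields ``IF medication_active(drug) THEN
    taking_drug_in_class(class_id)``; institutions swap in authoritative
    membership lists by editing the TSV.
    """
    rules: list[SupportingKnowledgeRule] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        class_id, drug = line.split("\t")[:2]
        drug = normalize_drug(drug)
        rules.append(
            SupportingKnowledgeRule(
                sk_id=f"class-{class_id}-{drug.replace(' ', '-')}",
                premises=(Pattern(F_MED_ACTIVE, (drug,)),),
                guards=(),
                derived=Pattern(F_IN_DRUG_CLASS, (class_id,)),
            )
        )
    return rules


def genotype_class_rule(sk_id: str, gene: str, diplotype: str, phenotype_class: str) -> SupportingKnowledgeRule:
    """Exact-diplotype phenotype rule, e.g. CYP2C9 *2/*3 -> poor_metabolizer."""
    return SupportingKnowledgeRule(
        sk_id=sk_id,
        premises=(Pattern(F_GENOTYPE, (gene, normalize_diplotype(diplotype))),),
        guards=(),
        derived=Pattern(F_PHENOTYPE_CLASS, (gene, phenotype_class)),
    )


def default_supporting_knowledge() -> list[SupportingKnowledgeRule]:
    """The packaged illustrative supporting-knowledge set.

    Covers the worked examples: poor-metabolizer diplotype classes for
    CYP2C9/CYP2C19/CYP2D6, the age<18 -> child rule, and drug-class
    membership for CYP2D6 inhibitors / CYP2D6 substrates.  Membership lists
    and diplotype tables are ILLUSTRATIVE placeholders for institutional
    content, not clinically authoritative.
    """
    from .fixtures import data_path  # local import to avoid a cycle

    rules = load_sk_rules(data_path("supporting_knowledge.yaml"))
    rules += drug_class_rules_from_tsv(data_path("drug_classes.tsv"))
    return rules
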
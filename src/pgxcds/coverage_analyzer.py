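"""EMR data-availability (coverage) analysis.

Given a rule catalog and a capability profile describing how each
clinical-data field is captured in an institution's EMR, compute the
fraction of rules executable under three nested scenarios:

* ``EMR_ALONE`` — only fields already captured as discrete data count;
* ``EMR_PLUS_KNOWLEDGE`` — adds fields satisfiable once supporting
  knowledge (phenotype classes, drug classes, demographic classes) exists;
* ``EMR_PLUS_EXPANSION`` — further adds fields judged feasible to capture:
  disease-status definitions, pathology/microbiology data-entry fields,
  and free-text lab values parseable without full NLP.

Fields requiring full NLP, and fields absent outright, are never
satisfiable, which caps achievable coverage below 100%.  Rules not
executable even with supporting knowledge are attributed to the
expansion categories whose absence blocks them.
"""

from __future__ import annotations

import fnmatch
import json
from dataclasses import dataclass, field as dc_field
from enum import Enum
from pathlib import Path
from typing import Any, Mapping

import yaml

from .certainty_classifier import CertaintyLexicon, classify_rule
from .errors import (
    CatalogFormatError,
    EmptyCatalogError,
    MissingCategoryError,
    ProfileConflictError,
)
from .rounding import pct
from .rule_model import (
    ClinicalDataField,
    FieldKind,
    PGxRule,
    PresentationType,
    RuleCatalog,
    SupportCategory,
    antecedent_fields,
)


class AvailabilityStatus(str, Enum):
    DISCRETE = "DISCRETE"
    REQUIRES_SUPPORTING_KNOWLEDGE = "REQUIRES_SUPPORTING_KNOWLEDGE"
    EXPANSION_DISEASE_STATUS_DEFINITION = "EXPANSION_DISEASE_STATUS_DEFINITION"
    EXPANSION_PATHOLOGY_FIELD = "EXPANSION_PATHOLOGY_FIELD"
    EXPANSION_MICROBIOLOGY_FIELD = "EXPANSION_MICROBIOLOGY_FIELD"
    EXPANSION_PARSEABLE_FREE_TEXT = "EXPANSION_PARSEABLE_FREE_TEXT"
    REQUIRES_FULL_NLP = "REQUIRES_FULL_NLP"
    ABSENT = "ABSENT"


EXPANSION_STATUSES = frozenset(
    {
        AvailabilityStatus.EXPANSION_DISEASE_STATUS_DEFINITION,
        AvailabilityStatus.EXPANSION_PATHOLOGY_FIELD,
        AvailabilityStatus.EXPANSION_MICROBIOLOGY_FIELD,
        AvailabilityStatus.EXPANSION_PARSEABLE_FREE_TEXT,
    }
)

# statuses that can leave a rule blocked beyond the supporting-knowledge scenario
BLOCKING_STATUSES = EXPANSION_STATUSES | {
    AvailabilityStatus.REQUIRES_FULL_NLP,
    AvailabilityStatus.ABSENT,
}


class Scenario(str, Enum):
    EMR_ALONE = "EMR_ALONE"
    EMR_PLUS_KNOWLEDGE = "EMR_PLUS_KNOWLEDGE"
    EMR_PLUS_EXPANSION = "EMR_PLUS_EXPANSION"

    @property
    def satisfied_statuses(self) -> frozenset[AvailabilityStatus]:
        return _SATISFIED[self]


_SATISFIED = {
    Scenario.EMR_ALONE: frozenset({AvailabilityStatus.DISCRETE}),
    Scenario.EMR_PLUS_KNOWLEDGE: frozenset(
        {AvailabilityStatus.DISCRETE, AvailabilityStatus.REQUIRES_SUPPORTING_KNOWLEDGE}
    ),
    Scenario.EMR_PLUS_EXPANSION: frozenset(
        {AvailabilityStatus.DISCRETE, AvailabilityStatus.REQUIRES_SUPPORTING_KNOWLEDGE}
    )
    | EXPANSION_STATUSES,
}

SCENARIO_ORDER = (Scenario.EMR_ALONE, Scenario.EMR_PLUS_KNOWLEDGE, Scenario.EMR_PLUS_EXPANSION)


# ---------------------------------------------------------------------------
# capability profile


@dataclass(frozen=True)
class PatternMatcher:
    kind: FieldKind | None
    detail_glob: str
    status: AvailabilityStatus

    def matches(self, field: ClinicalDataField) -> bool:
        if self.kind is not None and field.kind is not self.kind:
            return False
        return fnmatch.fnmatchcase(field.detail.lower(), self.detail_glob.lower())


@dataclass
class EMRCapabilityProfile:
    """Field -> availability-status map: exact ids beat (kind, detail) patterns."""

    exact: dict[str, AvailabilityStatus] = dc_field(default_factory=dict)
    patterns: list[PatternMatcher] = dc_field(default_factory=list)
    default_status: AvailabilityStatus = AvailabilityStatus.ABSENT

    def status_for(self, field: ClinicalDataField) -> AvailabilityStatus:
        if field.field_id in self.exact:
            return self.exact[field.field_id]
        hits = {m.status for m in self.patterns if m.matches(field)}
        if len(hits) > 1:
            raise ProfileConflictError(
                f"field {field.field_id!r} matched by patterns with conflicting statuses: "
                + ", ".join(sorted(s.value for s in hits))
            )
        if hits:
            return next(iter(hits))
        return self.default_status

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "EMRCapabilityProfile":
        profile = cls()
        if "default_status" in doc:
            profile.default_status = AvailabilityStatus(doc["default_status"])
        seen_exact: set[str] = set()
        seen_patterns: set[tuple[Any, str]] = set()
        for i, entry in enumerate(doc.get("entries") or []):
            try:
                match, status = entry["match"], AvailabilityStatus(entry["status"])
            except (KeyError, ValueError) as exc:
                raise CatalogFormatError(f"bad profile entry: {exc}", context=f"entries[{i}]") from exc
            if "field_id" in match:
                fid = str(match["field_id"])
                if fid in seen_exact:
                    raise ProfileConflictError(f"field_id {fid!r} listed twice in profile")
                seen_exact.add(fid)
                profile.exact[fid] = status
            else:
                kind = FieldKind(match["kind"]) if match.get("kind") else None
                glob = str(match.get("detail", "*"))
                key = (kind, glob)
                if key in seen_patterns:
                    raise ProfileConflictError(f"pattern {key!r} listed twice in profile")
                seen_patterns.add(key)
                profile.patterns.append(PatternMatcher(kind, glob, status))
        return profile

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EMRCapabilityProfile":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, Mapping):
            raise CatalogFormatError("profile file must be a mapping", context=str(path))
        return cls.from_dict(doc)

    def to_dict(self) -> dict[str, Any]:
        entries: list[dict[str, Any]] = [
            {"match": {"field_id": fid}, "status": st.value} for fid, st in sorted(self.exact.items())
        ]
        entries += [
            {
                "match": {"kind": m.kind.value if m.kind else None, "detail": m.detail_glob},
                "status": m.status.value,
            }
            for m in self.patterns
        ]
        return {"default_status": self.default_status.value, "entries": entries}


# ---------------------------------------------------------------------------
# executability and coverage


def rule_executable(rule: PGxRule, profile: EMRCapabilityProfile, scenario: Scenario) -> bool:
    """True iff every required field's status is satisfied under ``scenario``."""
    satisfied = scenario.satisfied_statuses
    return all(profile.status_for(f) in satisfied for f in antecedent_fields(rule).all_fields)


@dataclass
class ScenarioCoverage:
    executable: int
    total: int
    percent: int


@dataclass
class CoverageReport:
    scenarios: dict[Scenario, ScenarioCoverage]
    attribution: dict[AvailabilityStatus, tuple[int, int]]  # status -> (count, percent of total)
    attribution_mode: str
    total: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "total": self.total,
                "attribution_mode": self.attribution_mode,
                "scenarios": {
                    s.value: {
                        "executable": c.executable,
                        "total": c.total,
                        "percent": c.percent,
                    }
                    for s, c in self.scenarios.items()
                },
                "attribution": {
                    s.value: {"count": c, "percent": p} for s, (c, p) in self.attribution.items()
                },
            },
            indent=2,
            sort_keys=True,
        )

    def scenarios_tsv(self) -> str:
        lines = ["scenario\texecutable\ttotal\tpercent"]
        for s in SCENARIO_ORDER:
            c = self.scenarios[s]
            lines.append(f"{s.value}\t{c.executable}\t{c.total}\t{c.percent}")
        return "\n".join(lines) + "\n"

    def attribution_tsv(self) -> str:
        lines = ["blocking_category\tcount\tpercent"]
        for s in sorted(self.attribution, key=lambda s: s.value):
            c, p = self.attribution[s]
            lines.append(f"{s.value}\t{c}\t{p}")
        return "\n".join(lines) + "\n"


def coverage(
    catalog: RuleCatalog,
    profile: EMRCapabilityProfile,
    attribution: str = "any",
) -> CoverageReport:
    """Three-scenario coverage plus blocking-category attribution.

    Attribution counts a rule toward category C iff it requires at least
    one field with status C and is not executable under
    ``EMR_PLUS_KNOWLEDGE``.  ``attribution='any'`` counts a rule under
    every blocking category it needs (categories may overlap);
    ``'sole'`` only when C is its unique blocking category.
    """
    if not catalog.rules:
        raise EmptyCatalogError("cannot compute coverage of an empty catalog")
    if attribution not in ("any", "sole"):
        raise ValueError(f"attribution mode must be 'any' or 'sole', got {attribution!r}")
    total = len(catalog.rules)
    executable = {s: 0 for s in Scenario}
    blocked_counts = {s: 0 for s in BLOCKING_STATUSES}
    for rule in catalog.rules:
        statuses = {profile.status_for(f) for f in antecedent_fields(rule).all_fields}
        for scenario in Scenario:
            if statuses <= scenario.satisfied_statuses:
                executable[scenario] += 1
        if not statuses <= Scenario.EMR_PLUS_KNOWLEDGE.satisfied_statuses:
            blocking = statuses & BLOCKING_STATUSES
            if attribution == "any":
                for s in blocking:
                    blocked_counts[s] += 1
            elif len(blocking) == 1:
                blocked_counts[next(iter(blocking))] += 1
    scenarios = {
        s: ScenarioCoverage(executable=executable[s], total=total, percent=pct(executable[s], total))
        for s in Scenario
    }
    attribution_out = {
        s: (c, pct(c, total)) for s, c in sorted(blocked_counts.items(), key=lambda kv: kv[0].value) if c
    }
    return CoverageReport(
        scenarios=scenarios, attribution=attribution_out, attribution_mode=attribution, total=total
    )


# ---------------------------------------------------------------------------
# category distribution (general categories x presentation types)


@dataclass
class CategoryDistribution:
    table: dict[SupportCategory, dict[PresentationType, int]]
    category_counts: dict[SupportCategory, int]
    presentation_counts: dict[PresentationType, int]
    total: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "total": self.total,
                "categories": {
                    c.value: {
                        "count": self.category_counts[c],
                        "by_presentation": {t.value: n for t, n in self.table[c].items() if n},
                    }
                    for c in self.table
                },
                "presentation_marginals": {t.value: n for t, n in self.presentation_counts.items()},
            },
            indent=2,
            sort_keys=True,
        )


def category_distribution(
    catalog: RuleCatalog, lexicon: CertaintyLexicon | None = None
) -> CategoryDistribution:
    """Cross-tabulate rules by support category and presentation type.

    Rules without a pre-assigned presentation type are classified on the
    fly; a rule without a general category is an error.
    """
    if not catalog.rules:
        raise EmptyCatalogError("cannot tabulate an empty catalog")
    table: dict[SupportCategory, dict[PresentationType, int]] = {
        c: {t: 0 for t in PresentationType} for c in SupportCategory
    }
    for rule in catalog.rules:
        if rule.general_category is None:
            raise MissingCategoryError(f"rule {rule.rule_id!r} lacks a general category")
        ptype = rule.presentation_type or classify_rule(rule, lexicon)
        table[rule.general_category][ptype] += 1
    category_counts = {c: sum(row.values()) for c, row in table.items()}
    presentation_counts = {t: sum(table[c][t] for c in SupportCategory) for t in PresentationType}
    return CategoryDistribution(
        table=table,
        category_counts=category_counts,
        presentation_counts=presentation_counts,
        total=len(catalog.rules),
    )
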
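"""Certainty-based presentation-type classification of consequent statements.

Drug-label statements differ in how actionable they are.  An alert built
from a statement is presented as one of three types:

* ``WARNING`` — potential consequences are specified (any certainty);
* ``RECOMMENDATION`` — a clear action is specified with medium-to-high
  certainty language ("should", "will", "is", ...);
* ``INFORMATION`` — everything else, including actions hedged with
  low-certainty language ("might", "may", "could").

When a statement qualifies as more than one type the higher-severity type
wins (warning beats recommendation beats information).  Certainty is read
off the statement text with small word lexicons; whether an action is
*clear* and whether consequences are specified are curator annotations on
the statement, since neither is reliably recoverable from single-sentence
lexical cues.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
import yaml

from .errors import EmptyCatalogError, EmptyStatementError
from .rounding import pct
from .rule_model import (
    ActionSpecificity,
    PGxRule,
    PresentationType,
    RuleCatalog,
    ThenStatement,
)

DEFAULT_LOW_TERMS = frozenset({"might", "may", "could"})
DEFAULT_HIGH_TERMS = frozenset({"should", "will", "are", "is", "must", "was", "do"})
# suggestion-only cues for the consequence annotation; they never set the flag
DEFAULT_CONSEQUENCE_TERMS = frozenset({"risk", "caution", "adverse", "toxicity", "bleeding", "fatal"})


@dataclass(frozen=True)
class CertaintyLexicon:
    low_terms: frozenset[str] = DEFAULT_LOW_TERMS
    high_terms: frozenset[str] = DEFAULT_HIGH_TERMS
    consequence_terms: frozenset[str] = DEFAULT_CONSEQUENCE_TERMS

    def __post_init__(self) -> None:
        for name in ("low_terms", "high_terms", "consequence_terms"):
            for term in getattr(self, name):
                if term != term.lower() or not re.fullmatch(r"[a-z'\-]+", term):
                    raise ValueError(f"{name} entry {term!r} must be a lowercase single token")
        if self.low_terms & self.high_terms:
            raise ValueError("low_terms and high_terms must be disjoint")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CertaintyLexicon":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            low_terms=frozenset(doc.get("low_terms", DEFAULT_LOW_TERMS)),
            high_terms=frozenset(doc.get("high_terms", DEFAULT_HIGH_TERMS)),
            consequence_terms=frozenset(doc.get("consequence_terms", DEFAULT_CONSEQUENCE_TERMS)),
        )


class Certainty(str, Enum):
    LOW = "LOW"
    MEDIUM_HIGH = "MEDIUM_HIGH"
    NONE = "NONE"


@dataclass(frozen=True)
class CertaintyLevel:
    value: Certainty
    matched_tokens: tuple[tuple[str, int], ...]  # (token, character offset)


_WORD_RE = re.compile(r"[a-z'\-]+", re.IGNORECASE)


def _scan(text: str, terms: frozenset[str]) -> list[tuple[str, int]]:
    hits = []
    for m in _WORD_RE.finditer(text):
        token = m.group(0).lower()
        if token in terms:
            hits.append((token, m.start()))
    return hits


def extract_certainty(text: str, lexicon: CertaintyLexicon | None = None) -> CertaintyLevel:
    """Scan statement text for certainty cues (case-insensitive, whole words).

    A low-certainty hit dominates: hedged language downgrades the whole
    statement even when high-certainty words co-occur.  Substrings never
    match ("may" inside "Maybe" is not a hit).
    """
    if not text:
        raise EmptyStatementError("statement text is empty")
    lexicon = lexicon or CertaintyLexicon()
    low_hits = _scan(text, lexicon.low_terms)
    if low_hits:
        return CertaintyLevel(Certainty.LOW, tuple(low_hits))
    high_hits = _scan(text, lexicon.high_terms)
    if high_hits:
        return CertaintyLevel(Certainty.MEDIUM_HIGH, tuple(high_hits))
    return CertaintyLevel(Certainty.NONE, ())


def suggest_consequence_terms(text: str, lexicon: CertaintyLexicon | None = None) -> tuple[tuple[str, int], ...]:
    """Consequence-cue hits, for curator review only; never sets the flag."""
    if not text:
        raise EmptyStatementError("statement text is empty")
    lexicon = lexicon or CertaintyLexicon()
    return tuple(_scan(text, lexicon.consequence_terms))


def classify_statement(stmt: ThenStatement, lexicon: CertaintyLexicon | None = None) -> PresentationType:
    """Assign a presentation type to one consequent statement.

    Decision order encodes the severity tie-breaks: consequences make a
    warning regardless of certainty; a clear action stated with
    medium-to-high certainty makes a recommendation; everything else is
    information only.
    """
    if stmt.consequence_flag:
        return PresentationType.WARNING
    if (
        stmt.action_specificity is ActionSpecificity.CLEAR
        and extract_certainty(stmt.text, lexicon).value is Certainty.MEDIUM_HIGH
    ):
        return PresentationType.RECOMMENDATION
    return PresentationType.INFORMATION


def classify_rule(rule: PGxRule, lexicon: CertaintyLexicon | None = None) -> PresentationType:
    """Rule-level type: the maximum severity across its consequents."""
    return max(
        (classify_statement(s, lexicon) for s in rule.consequents),
        key=lambda t: t.severity,
    )


@dataclass
class DistributionReport:
    """Presentation-type counts and rounded percentages over a catalog."""

    counts: dict[PresentationType, int]
    percentages: dict[PresentationType, int]
    total: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "total": self.total,
                "counts": {t.value: self.counts[t] for t in PresentationType},
                "percentages": {t.value: self.percentages[t] for t in PresentationType},
            },
            indent=2,
            sort_keys=True,
        )

    def to_tsv(self) -> str:
        lines = ["type\tcount\tpercent"]
        for t in sorted(PresentationType, key=lambda t: -t.severity):
            lines.append(f"{t.value}\t{self.counts[t]}\t{self.percentages[t]}")
        return "\n".join(lines) + "\n"


def classify_catalog(
    catalog: RuleCatalog, lexicon: CertaintyLexicon | None = None
) -> tuple[dict[str, PresentationType], DistributionReport]:
    """Classify every rule and tally the presentation-type distribution."""
    if not catalog.rules:
        raise EmptyCatalogError("cannot classify an empty catalog")
    assignments = {rule.rule_id: classify_rule(rule, lexicon) for rule in catalog.rules}
    counts = {t: 0 for t in PresentationType}
    for t in assignments.values():
        counts[t] += 1
    total = len(catalog.rules)
    percentages = {t: pct(c, total) for t, c in counts.items()}
    return assignments, DistributionReport(counts=counts, percentages=percentages, total=total)
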
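"""Evidence-catalog statistics for PGx knowledge resources.

Covers three analyses used to judge whether curated resources supply the
knowledge a decision-support rule base needs:

* citation-set overlap between two resources (e.g. articles cited by a
  regulator's biomarker table vs. articles curated in a PGx knowledge
  base), with the percentage taken over the union;
* distribution of evidence-category tags on curated publications —
  clinical outcome (CO), pharmacodynamics (PD), pharmacokinetics (PK),
  functional assays (FA), genotype (GN); a publication may carry several;
* a per-drug encoded-knowledge matrix (which structured knowledge forms a
  resource holds for each drug) and its marginal tallies.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .errors import EmptyMatrixError, EmptySetError, EmptySetsError
from .rounding import pct

EVIDENCE_CATEGORIES = ("CO", "PD", "PK", "FA", "GN")
PHENOTYPIC_CATEGORIES = frozenset({"CO", "PD", "PK", "FA"})


def normalize_article_id(article_id: str) -> str:
    return article_id.strip().casefold()


@dataclass
class CitationSet:
    resource: str
    articles: frozenset[str]

    @classmethod
    def from_ids(cls, resource: str, ids: Iterable[str]) -> "CitationSet":
        return cls(resource=resource, articles=frozenset(normalize_article_id(a) for a in ids))

    @classmethod
    def from_file(cls, path: str | Path, resource: str | None = None) -> "CitationSet":
        """One article id per line, or two-column TSV (resource, article_id)."""
        ids: list[str] = []
        name = resource or Path(path).stem
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 2:
                name = parts[0]
                ids.append(parts[1])
            else:
                ids.append(parts[0])
        return cls.from_ids(name, ids)

    def __len__(self) -> int:
        return len(self.articles)


@dataclass(frozen=True)
class PublicationRecord:
    article_id: str
    categories: frozenset[str] = frozenset()
    designated_for_pair: bool = True

    def __post_init__(self) -> None:
        bad = self.categories - set(EVIDENCE_CATEGORIES)
        if bad:
            raise ValueError(f"unknown evidence categor(ies) {sorted(bad)}")


def load_publications(path: str | Path) -> list[PublicationRecord]:
    """TSV: article_id, semicolon-joined categories, designated flag (true/false)."""
    out: list[PublicationRecord] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("article_id\t"):
            continue
        parts = line.split("\t")
        cats = frozenset(c for c in parts[1].split(";") if c) if len(parts) > 1 else frozenset()
        designated = parts[2].strip().lower() in ("1", "true", "yes") if len(parts) > 2 else True
        out.append(PublicationRecord(normalize_article_id(parts[0]), cats, designated))
    return out


# ---------------------------------------------------------------------------
# overlap


@dataclass(frozen=True)
class OverlapStats:
    size_a: int
    size_b: int
    intersection: int
    union: int
    pct_of_union: int


def overlap_stats(a: CitationSet, b: CitationSet) -> OverlapStats:
    """Exact set overlap; the percentage is of the union (inclusion-exclusion)."""
    if not a.articles and not b.articles:
        raise EmptySetsError("both citation sets are empty")
    inter = len(a.articles & b.articles)
    union = len(a.articles | b.articles)
    return OverlapStats(
        size_a=len(a),
        size_b=len(b),
        intersection=inter,
        union=union,
        pct_of_union=pct(inter, union),
    )


# ---------------------------------------------------------------------------
# evidence-category distribution


def category_distribution(pubs: Sequence[PublicationRecord]) -> dict[str, tuple[int, int]]:
    """Per-category (count, percent of publications).

    A publication tagged with k categories contributes to k counts, so the
    percentages need not sum to 100.
    """
    if not pubs:
        raise EmptySetError("no publication records")
    counts = {c: 0 for c in EVIDENCE_CATEGORIES}
    for p in pubs:
        for c in p.categories:
            counts[c] += 1
    n = len(pubs)
    return {c: (counts[c], pct(counts[c], n)) for c in EVIDENCE_CATEGORIES}


def undesignated_fraction(overlap_pubs: Sequence[PublicationRecord]) -> tuple[int, int]:
    """(count, percent) of records not designated as evidence for the pair."""
    if not overlap_pubs:
        raise EmptySetError("no publication records")
    count = sum(1 for p in overlap_pubs if not p.designated_for_pair)
    return count, pct(count, len(overlap_pubs))


# ---------------------------------------------------------------------------
# encoded-knowledge matrix


class KnowledgeForm(str, Enum):
    PATHWAY_EVIDENCE = "PATHWAY_EVIDENCE"
    VARIANT_EVIDENCE = "VARIANT_EVIDENCE"
    GENOTYPE_DATA = "GENOTYPE_DATA"
    PHENOTYPE_DATA = "PHENOTYPE_DATA"
    CLINICAL_PGX_SECTION = "CLINICAL_PGX_SECTION"


class AvailabilityClass(str, Enum):
    ENCODED = "ENCODED"
    TAGGED = "TAGGED"
    COMPUTABLE = "COMPUTABLE"


FORM_ORDER = tuple(KnowledgeForm)


@dataclass
class KnowledgeMatrix:
    """Drug -> set of encoded-knowledge forms, plus availability-class tags."""

    forms: dict[str, frozenset[KnowledgeForm]]
    classes: dict[str, frozenset[AvailabilityClass]] = dc_field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.forms)

    def to_tsv(self) -> str:
        header = "drug\t" + "\t".join(f.value.lower() for f in FORM_ORDER)
        lines = [header]
        for drug in sorted(self.forms):
            marks = "\t".join("x" if f in self.forms[drug] else "" for f in FORM_ORDER)
            lines.append(f"{drug}\t{marks}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "KnowledgeMatrix":
        lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
        header = lines[0].split("\t")[1:]
        forms_by_col = [KnowledgeForm(h.strip().upper()) for h in header]
        forms: dict[str, frozenset[KnowledgeForm]] = {}
        for ln in lines[1:]:
            parts = ln.split("\t")
            drug = parts[0].strip()
            if drug in forms:
                raise ValueError(f"drug {drug!r} repeated in matrix")
            marks = parts[1:] + [""] * (len(forms_by_col) - (len(parts) - 1))
            forms[drug] = frozenset(f for f, m in zip(forms_by_col, marks) if m.strip().lower() == "x")
        return cls(forms=forms)


@dataclass
class MatrixSummary:
    drugs: int
    per_form: dict[KnowledgeForm, int]  # how many drugs carry each form
    per_drug: dict[str, int]  # how many forms each drug carries


def knowledge_matrix_summary(matrix: KnowledgeMatrix) -> MatrixSummary:
    if not matrix.forms:
        raise EmptyMatrixError("knowledge matrix is empty")
    per_form = {f: sum(1 for forms in matrix.forms.values() if f in forms) for f in KnowledgeForm}
    per_drug = {drug: len(forms) for drug, forms in matrix.forms.items()}
    return MatrixSummary(drugs=len(matrix.forms), per_form=per_form, per_drug=per_drug)
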
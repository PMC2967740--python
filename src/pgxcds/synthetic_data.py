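"""Seeded generators for synthetic catalogs, patients, profiles and citations.

Every generator is a pure function of its :class:`GeneratorSpec` (or of the
explicit arguments plus seed): one ``random.Random`` stream per call, no
global state, identical inputs give bit-identical outputs.  Generated
catalogs carry their ground truth (planted presentation labels, support
categories, and per-field availability statuses) in catalog metadata so
recovery tests can compare exactly.

Default mixes emulate the published study conditions: a 39/39/22
information/recommendation/warning presentation mix, a 24% benefit /
13% testing / 9% coadministration / 4% communication category profile with
the remainder split across dose adjustment, monitoring and pre-treatment
consideration, and an availability mix in which roughly a third of rules
are executable from discrete data alone.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field as dc_field
from typing import Any, Mapping

from .coverage_analyzer import AvailabilityStatus, EMRCapabilityProfile
from .errors import InvalidOverlapError
from .evidence_catalog import EVIDENCE_CATEGORIES, CitationSet, PublicationRecord
from .rule_evaluator import PatientRecord
from .rule_model import (
    ActionSpecificity,
    And,
    ClinicalDataField,
    Condition,
    FieldKind,
    FieldSource,
    PGxRule,
    Predicate,
    PresentationType,
    RuleCatalog,
    SupportCategory,
    ThenStatement,
    normalize_diplotype,
)

DEFAULT_PRESENTATION_MIX: dict[str, float] = {
    PresentationType.INFORMATION.value: 0.39,
    PresentationType.RECOMMENDATION.value: 0.39,
    PresentationType.WARNING.value: 0.22,
}

DEFAULT_CATEGORY_MIX: dict[str, float] = {
    SupportCategory.DOSE_ADJUSTMENT.value: 0.20,
    SupportCategory.PATIENT_MONITORING.value: 0.15,
    SupportCategory.PRE_TREATMENT_CONSIDERATION.value: 0.15,
    SupportCategory.BENEFIT_PREDICTION.value: 0.24,
    SupportCategory.TESTING_GUIDANCE.value: 0.13,
    SupportCategory.COADMINISTRATION.value: 0.09,
    SupportCategory.PATIENT_COMMUNICATION.value: 0.04,
}

DEFAULT_AVAILABILITY_MIX: dict[str, float] = {
    AvailabilityStatus.DISCRETE.value: 0.45,
    AvailabilityStatus.REQUIRES_SUPPORTING_KNOWLEDGE.value: 0.20,
    AvailabilityStatus.EXPANSION_DISEASE_STATUS_DEFINITION.value: 0.08,
    AvailabilityStatus.EXPANSION_PATHOLOGY_FIELD.value: 0.02,
    AvailabilityStatus.EXPANSION_MICROBIOLOGY_FIELD.value: 0.12,
    AvailabilityStatus.EXPANSION_PARSEABLE_FREE_TEXT.value: 0.06,
    AvailabilityStatus.REQUIRES_FULL_NLP.value: 0.05,
    AvailabilityStatus.ABSENT.value: 0.02,
}

DEFAULT_ALLELE_FREQUENCIES: dict[str, dict[str, float]] = {
    "CYP2C9": {"*1": 0.80, "*2": 0.12, "*3": 0.08},
    "CYP2C19": {"*1": 0.75, "*2": 0.18, "*3": 0.07},
    "CYP2D6": {"*1": 0.70, "*4": 0.20, "*5": 0.10},
}

_DRUG_POOL = (
    "abacavir", "atomoxetine", "atorvastatin", "azathioprine", "busulfan",
    "capecitabine", "carbamazepine", "celecoxib", "cetuximab", "clopidogrel",
    "dasatinib", "erlotinib", "fluoxetine hcl", "imatinib mesylate",
    "irinotecan", "isoniazid", "maraviroc", "panitumumab", "rasburicase",
    "rifampin", "trastuzumab", "valproic acid", "voriconazole", "warfarin",
)

_DISEASE_POOL = (
    "hepatic impairment", "renal impairment", "asm", "gist", "dfsp",
    "epilepsy", "depression", "hiv infection", "tuberculosis", "colorectal cancer",
)

_GENE_POOL = ("CYP2C9", "CYP2C19", "CYP2D6", "TPMT", "UGT1A1", "VKORC1")


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters for one generator call.

    ``mixes`` overrides any of the default categorical weight maps, keyed
    ``presentation``, ``category``, ``availability``, ``allele_frequencies``.
    """

    seed: int
    n: int = 1
    mixes: Mapping[str, Any] = dc_field(default_factory=dict)

    def mix(self, name: str, default: Mapping[str, Any]) -> Mapping[str, Any]:
        chosen = self.mixes.get(name, default)
        if name != "allele_frequencies":
            weights = list(chosen.values())
            if any(w < 0 for w in weights) or sum(weights) <= 0:
                raise ValueError(f"mix {name!r}: weights must be non-negative and sum > 0")
        return chosen


def _weighted_choice(rng: random.Random, mix: Mapping[str, float]) -> str:
    keys = list(mix.keys())
    return rng.choices(keys, weights=[mix[k] for k in keys], k=1)[0]


# ---------------------------------------------------------------------------
# rule catalogs


def _consequent_for(label: PresentationType, drug: str, rng: random.Random) -> ThenStatement:
    if label is PresentationType.WARNING:
        return ThenStatement(
            f"there is an increased risk of adverse events with {drug}", ActionSpecificity.NONE, True
        )
    if label is PresentationType.RECOMMENDATION:
        pctv = rng.choice((25, 50, 75))
        return ThenStatement(
            f"the dose of {drug} should be reduced by {pctv}%", ActionSpecificity.CLEAR, False
        )
    return ThenStatement(f"a dose adjustment of {drug} may be considered", ActionSpecificity.VAGUE, False)


def gen_rule_catalog(spec: GeneratorSpec) -> RuleCatalog:
    """Synthetic catalog with known (planted) labels, categories and statuses.

    Each rule's consequent text and annotations are chosen so the
    certainty classifier provably assigns the planted presentation label;
    each antecedent field carries a planted availability status.  Ground
    truth lives in ``catalog.metadata['ground_truth']``.
    """
    if spec.n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(spec.seed)
    presentation_mix = spec.mix("presentation", DEFAULT_PRESENTATION_MIX)
    category_mix = spec.mix("category", DEFAULT_CATEGORY_MIX)
    availability_mix = spec.mix("availability", DEFAULT_AVAILABILITY_MIX)

    rules: list[PGxRule] = []
    gt_presentation: dict[str, str] = {}
    gt_category: dict[str, str] = {}
    gt_field_status: dict[str, str] = {}

    for i in range(spec.n):
        rule_id = f"syn-{i:04d}"
        drug = rng.choice(_DRUG_POOL)
        gene = rng.choice(_GENE_POOL)
        label = PresentationType(_weighted_choice(rng, presentation_mix))
        category = SupportCategory(_weighted_choice(rng, category_mix))

        conds: list[Condition] = [
            Condition.make(
                Predicate.MEDICATION_ACTIVE,
                {"drug": drug},
                ClinicalDataField(
                    f"{rule_id}_med", FieldKind.MEDICATION, FieldSource.INPATIENT_OUTPATIENT_DB, drug
                ),
            )
        ]
        if rng.random() < 0.5:
            conds.append(
                Condition.make(
                    Predicate.HAS_DISEASE,
                    {"disease": rng.choice(_DISEASE_POOL)},
                    ClinicalDataField(
                        f"{rule_id}_disease",
                        FieldKind.DISEASE_STATUS,
                        FieldSource.INPATIENT_OUTPATIENT_DB,
                        "disease status",
                    ),
                )
            )
        if rng.random() < 0.7:
            conds.append(
                Condition.make(
                    Predicate.HAS_VARIANT,
                    {"gene": gene},
                    ClinicalDataField(
                        f"{rule_id}_variant", FieldKind.GERMLINE_VARIANT_STATUS, FieldSource.LABORATORY_DB, gene
                    ),
                )
            )
        antecedent = conds[0] if len(conds) == 1 else And(tuple(conds))
        for cond in conds:
            gt_field_status[cond.field.field_id] = _weighted_choice(rng, availability_mix)

        rules.append(
            PGxRule(
                rule_id=rule_id,
                drug=drug,
                biomarker=gene,
                antecedent=antecedent,
                consequents=[_consequent_for(label, drug, rng)],
                general_category=category,
                provenance="synthetic",
            )
        )
        gt_presentation[rule_id] = label.value
        gt_category[rule_id] = category.value

    return RuleCatalog(
        rules=rules,
        metadata={
            "name": "synthetic-catalog",
            "version": "1",
            "seed": spec.seed,
            "ground_truth": {
                "presentation": gt_presentation,
                "category": gt_category,
                "field_status": gt_field_status,
            },
        },
    )


def profile_from_catalog(catalog: RuleCatalog) -> EMRCapabilityProfile:
    """Capability profile realizing a synthetic catalog's planted statuses."""
    statuses = catalog.metadata.get("ground_truth", {}).get("field_status")
    if not statuses:
        raise ValueError("catalog carries no planted field statuses")
    return EMRCapabilityProfile(
        exact={fid: AvailabilityStatus(s) for fid, s in statuses.items()}
    )


def gen_capability_profile(spec: GeneratorSpec) -> EMRCapabilityProfile:
    """Profile over ``n`` generic field ids with statuses from the mix."""
    rng = random.Random(spec.seed)
    availability_mix = spec.mix("availability", DEFAULT_AVAILABILITY_MIX)
    exact = {
        f"f{i:04d}": AvailabilityStatus(_weighted_choice(rng, availability_mix)) for i in range(spec.n)
    }
    return EMRCapabilityProfile(exact=exact)


# ---------------------------------------------------------------------------
# patients


def gen_patient(spec: GeneratorSpec) -> PatientRecord:
    """One synthetic patient; genotypes drawn per-allele from stated frequencies."""
    rng = random.Random(spec.seed)
    freqs = spec.mix("allele_frequencies", DEFAULT_ALLELE_FREQUENCIES)
    genotypes: dict[str, str] = {}
    for gene in sorted(freqs):
        table = freqs[gene]
        a = _weighted_choice(rng, table)
        b = _weighted_choice(rng, table)
        genotypes[gene] = normalize_diplotype(f"{a}/{b}")
    meds = set(rng.sample(_DRUG_POOL, k=rng.randint(0, 4)))
    considered = set(rng.sample(_DRUG_POOL, k=rng.randint(0, 1)))
    diseases = set(rng.sample(_DISEASE_POOL, k=rng.randint(0, 2)))
    return PatientRecord(
        patient_id=f"pt-{spec.seed:06d}",
        age=rng.randint(0, 90),
        sex=rng.choice(("female", "male")),
        medications_active=meds,
        medications_considered=considered,
        disease_statuses=diseases,
        germline_genotypes=genotypes,
        tumor_genotypes=set(),
        lab_values={"inr": (round(rng.uniform(0.8, 4.0), 2), "ratio")},
    )


# ---------------------------------------------------------------------------
# citation sets and publication records


def gen_citation_sets(
    n_a: int, n_b: int, n_shared: int, seed: int
) -> tuple[CitationSet, CitationSet]:
    """Two citation sets with |A| = n_a, |B| = n_b, |A∩B| = n_shared exactly."""
    if n_shared > min(n_a, n_b):
        raise InvalidOverlapError(
            f"n_shared={n_shared} exceeds min(n_a={n_a}, n_b={n_b})"
        )
    rng = random.Random(seed)
    total = n_a + n_b - n_shared
    ids = [f"pmid:{1_000_000 + i}" for i in range(total)]
    rng.shuffle(ids)
    shared = ids[:n_shared]
    only_a = ids[n_shared : n_a]
    only_b = ids[n_a:]
    return (
        CitationSet.from_ids("resource-a", shared + only_a),
        CitationSet.from_ids("resource-b", shared + only_b),
    )


def gen_publications(
    n: int,
    category_counts: Mapping[str, int],
    seed: int,
    n_undesignated: int = 0,
) -> list[PublicationRecord]:
    """``n`` records with exactly the requested per-category tag counts.

    Each category's tags are planted on a seeded random subset of records,
    so multi-label overlap arises naturally while the marginal counts are
    exact.  ``n_undesignated`` records are flagged as not designated for
    the biomarker-drug pair.
    """
    bad = set(category_counts) - set(EVIDENCE_CATEGORIES)
    if bad:
        raise ValueError(f"unknown categor(ies) {sorted(bad)}")
    if any(k > n for k in category_counts.values()) or n_undesignated > n:
        raise ValueError("planted counts cannot exceed n")
    rng = random.Random(seed)
    tags: dict[int, set[str]] = {i: set() for i in range(n)}
    for cat in EVIDENCE_CATEGORIES:
        k = category_counts.get(cat, 0)
        for i in rng.sample(range(n), k):
            tags[i].add(cat)
    undesignated = set(rng.sample(range(n), n_undesignated))
    return [
        PublicationRecord(
            article_id=f"pmid:{2_000_000 + i}",
            categories=frozenset(tags[i]),
            designated_for_pair=i not in undesignated,
        )
        for i in range(n)
    ]
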
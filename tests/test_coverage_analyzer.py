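"""Coverage analysis: scenario nesting, oracle equivalence, attribution bounds."""

import random

import pytest

from pgxcds.coverage_analyzer import (
    AvailabilityStatus,
    EMRCapabilityProfile,
    PatternMatcher,
    Scenario,
    category_distribution,
    coverage,
    rule_executable,
)
from pgxcds.errors import EmptyCatalogError, MissingCategoryError, ProfileConflictError
from pgxcds.rule_model import (
    ClinicalDataField,
    FieldKind,
    PresentationType,
    RuleCatalog,
    SupportCategory,
    antecedent_fields,
)
from pgxcds.synthetic_data import GeneratorSpec, gen_rule_catalog, profile_from_catalog

D = AvailabilityStatus.DISCRETE
SK = AvailabilityStatus.REQUIRES_SUPPORTING_KNOWLEDGE
NLP = AvailabilityStatus.REQUIRES_FULL_NLP


def _all_discrete_profile(catalog):
    exact = {}
    for rule in catalog.rules:
        for f in antecedent_fields(rule).all_fields:
            exact[f.field_id] = D
    return EMRCapabilityProfile(exact=exact)


class TestScenarioSemantics:
    def test_satisfied_status_sets_strictly_nested(self):
        a = Scenario.EMR_ALONE.satisfied_statuses
        k = Scenario.EMR_PLUS_KNOWLEDGE.satisfied_statuses
        e = Scenario.EMR_PLUS_EXPANSION.satisfied_statuses
        assert a < k < e

    def test_discrete_only_rule_runs_on_emr_alone(self, worked_catalog):
        rule = worked_catalog.rules[0]  # no supporting-knowledge requirement
        profile = _all_discrete_profile(worked_catalog)
        assert rule_executable(rule, profile, Scenario.EMR_ALONE)

    def test_supporting_knowledge_field_needs_second_scenario(self, worked_catalog):
        rule = worked_catalog.rules[1]
        profile = _all_discrete_profile(worked_catalog)
        profile.exact["sk_cyp2c9_poor_metabolism"] = SK
        assert not rule_executable(rule, profile, Scenario.EMR_ALONE)
        assert rule_executable(rule, profile, Scenario.EMR_PLUS_KNOWLEDGE)

    def test_full_nlp_field_blocks_every_scenario(self, worked_catalog):
        rule = worked_catalog.rules[0]
        profile = _all_discrete_profile(worked_catalog)
        profile.exact["tumor_ckit_genotype"] = NLP
        for scenario in Scenario:
            assert not rule_executable(rule, profile, scenario)


class TestProfileMatching:
    def test_exact_beats_pattern(self):
        profile = EMRCapabilityProfile(
            exact={"f1": D},
            patterns=[PatternMatcher(FieldKind.MEDICATION, "*", NLP)],
        )
        f1 = ClinicalDataField("f1", FieldKind.MEDICATION, "INPATIENT_OUTPATIENT_DB", "x")
        assert profile.status_for(f1) is D

    def test_conflicting_patterns_raise(self):
        profile = EMRCapabilityProfile(
            patterns=[
                PatternMatcher(FieldKind.MEDICATION, "*", D),
                PatternMatcher(None, "warf*", NLP),
            ]
        )
        f = ClinicalDataField("f2", FieldKind.MEDICATION, "INPATIENT_OUTPATIENT_DB", "warfarin")
        with pytest.raises(ProfileConflictError):
            profile.status_for(f)

    def test_unmatched_field_gets_default(self):
        profile = EMRCapabilityProfile()
        f = ClinicalDataField("f3", FieldKind.LAB_VALUE, "LABORATORY_DB", "inr")
        assert profile.status_for(f) is AvailabilityStatus.ABSENT


class TestCoverage:
    def test_saturated_catalog_is_fully_covered(self, worked_catalog):
        report = coverage(worked_catalog, _all_discrete_profile(worked_catalog))
        for scenario in Scenario:
            assert report.scenarios[scenario].percent == 100
        assert report.attribution == {}

    def test_empty_catalog_rejected(self):
        with pytest.raises(EmptyCatalogError):
            coverage(RuleCatalog(rules=[]), EMRCapabilityProfile())

    def _oracle(self, catalog, profile):
        """Brute-force loop over rules x scenarios, independent of coverage()."""
        counts = {s: 0 for s in Scenario}
        for rule in catalog.rules:
            statuses = [profile.status_for(f) for f in antecedent_fields(rule).all_fields]
            for s in Scenario:
                if all(st in s.satisfied_statuses for st in statuses):
                    counts[s] += 1
        return counts

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        catalog = gen_rule_catalog(GeneratorSpec(seed=seed, n=seed % 4 * 10 + 10))
        profile = profile_from_catalog(catalog)
        report = coverage(catalog, profile)
        oracle = self._oracle(catalog, profile)
        for s in Scenario:
            assert report.scenarios[s].executable == oracle[s]

    def test_monotone_across_nested_scenarios(self):
        for seed in range(60):
            catalog = gen_rule_catalog(GeneratorSpec(seed=1000 + seed, n=12))
            report = coverage(catalog, profile_from_catalog(catalog))
            a = report.scenarios[Scenario.EMR_ALONE].executable
            k = report.scenarios[Scenario.EMR_PLUS_KNOWLEDGE].executable
            e = report.scenarios[Scenario.EMR_PLUS_EXPANSION].executable
            assert a <= k <= e

    def test_upgrading_a_field_never_decreases_coverage(self):
        rng = random.Random(99)
        catalog = gen_rule_catalog(GeneratorSpec(seed=4, n=25))
        profile = profile_from_catalog(catalog)
        before = coverage(catalog, profile)
        for fid in rng.sample(sorted(profile.exact), 10):
            upgraded = EMRCapabilityProfile(exact=dict(profile.exact))
            upgraded.exact[fid] = D
            after = coverage(catalog, upgraded)
            for s in Scenario:
                assert after.scenarios[s].executable >= before.scenarios[s].executable

    @pytest.mark.parametrize("mode", ["any", "sole"])
    def test_attribution_bounded_by_blocked_rules(self, mode):
        catalog = gen_rule_catalog(GeneratorSpec(seed=21, n=60))
        report = coverage(catalog, profile_from_catalog(catalog), attribution=mode)
        blocked = report.total - report.scenarios[Scenario.EMR_PLUS_KNOWLEDGE].executable
        assert all(count <= blocked for count, _ in report.attribution.values())
        if mode == "sole":  # sole-blocker counts partition a subset of blocked rules
            assert sum(count for count, _ in report.attribution.values()) <= blocked


class TestCategoryDistribution:
    def test_worked_catalog_presentation_marginals(self, worked_catalog):
        dist = category_distribution(worked_catalog)
        assert dist.presentation_counts == {
            PresentationType.RECOMMENDATION: 2,
            PresentationType.INFORMATION: 2,
            PresentationType.WARNING: 1,
        }
        assert sum(dist.category_counts.values()) == 5

    def test_single_rule_single_cell(self, warfarin):
        dist = category_distribution(RuleCatalog(rules=[warfarin]))
        assert dist.category_counts[SupportCategory.PRE_TREATMENT_CONSIDERATION] == 1
        assert dist.table[SupportCategory.PRE_TREATMENT_CONSIDERATION][PresentationType.WARNING] == 1

    def test_missing_category_rejected(self, warfarin):
        warfarin.general_category = None
        with pytest.raises(MissingCategoryError):
            category_distribution(RuleCatalog(rules=[warfarin]))

    def test_recovers_planted_category_mix_exactly(self):
        catalog = gen_rule_catalog(GeneratorSpec(seed=31, n=200))
        dist = category_distribution(catalog)
        planted = catalog.metadata["ground_truth"]["category"]
        expected = {c: 0 for c in SupportCategory}
        for v in planted.values():
            expected[SupportCategory(v)] += 1
        assert dist.category_counts == expected

    def test_marginals_agree_with_classifier_distribution(self):
        from pgxcds.certainty_classifier import classify_catalog

        catalog = gen_rule_catalog(GeneratorSpec(seed=32, n=80))
        dist = category_distribution(catalog)
        _, report = classify_catalog(catalog)
        assert dist.presentation_counts == report.counts
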
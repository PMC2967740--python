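"""Certainty extraction and presentation-type classification."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgxcds.certainty_classifier import (
    Certainty,
    CertaintyLexicon,
    classify_catalog,
    classify_rule,
    classify_statement,
    extract_certainty,
)
from pgxcds.errors import EmptyCatalogError, EmptyStatementError
from pgxcds.rule_model import (
    ActionSpecificity,
    PresentationType,
    RuleCatalog,
    ThenStatement,
)
from pgxcds.synthetic_data import GeneratorSpec, gen_rule_catalog


class TestExtractCertainty:
    @pytest.mark.parametrize(
        "text,level,token",
        [
            ("coadministration should be approached with caution", Certainty.MEDIUM_HIGH, "should"),
            ("the dose adjustment for Clopidogrel is unknown for the patient", Certainty.MEDIUM_HIGH, "is"),
            ("a dose reduction might help", Certainty.LOW, "might"),
            ("no verb of note here", Certainty.NONE, None),
        ],
    )
    def test_examples(self, text, level, token):
        got = extract_certainty(text)
        assert got.value is level
        if token is None:
            assert got.matched_tokens == ()
        else:
            assert token in {t for t, _ in got.matched_tokens}

    def test_word_boundaries_block_substring_hits(self):
        # "may" inside "Maybe" must not count
        assert extract_certainty("Maybe useful").value is Certainty.NONE
        assert extract_certainty("it may be useful").value is Certainty.LOW

    def test_low_dominates_high_in_mixed_statements(self):
        got = extract_certainty("the dose should be reduced and may be split")
        assert got.value is Certainty.LOW

    def test_matching_is_case_insensitive_with_offsets(self):
        got = extract_certainty("Should we act")
        assert got.value is Certainty.MEDIUM_HIGH
        assert got.matched_tokens == (("should", 0),)

    def test_empty_text_is_an_error(self):
        with pytest.raises(EmptyStatementError):
            extract_certainty("")

    def test_lexicons_must_be_disjoint(self):
        with pytest.raises(ValueError):
            CertaintyLexicon(low_terms=frozenset({"may"}), high_terms=frozenset({"may"}))

    @settings(derandomize=True, max_examples=50)
    @given(st.text(alphabet="abcdefghij MAYmight.", min_size=1, max_size=40))
    def test_none_iff_no_matched_tokens(self, text):
        got = extract_certainty(text)
        assert (got.value is Certainty.NONE) == (got.matched_tokens == ())


def _stmt(text, action, consequence):
    return ThenStatement(text, action, consequence)


class TestClassifyStatement:
    @pytest.mark.parametrize(
        "text,action,consequence,expected",
        [
            # worked examples with their printed labels
            ("recommended dose of Gleevec is 400 mg/day", ActionSpecificity.CLEAR, False, PresentationType.RECOMMENDATION),
            ("the dose adjustment for Clopidogrel is unknown for the patient", ActionSpecificity.NONE, False, PresentationType.INFORMATION),
            ("coadministration should be approached with caution", ActionSpecificity.VAGUE, True, PresentationType.WARNING),
            # "should" alone is not enough without a clear action
            ("the dose of Atomoxetine should be adjusted", ActionSpecificity.VAGUE, False, PresentationType.INFORMATION),
            # warning wins the tie against a qualifying recommendation
            ("the dose should be halved to avoid toxicity", ActionSpecificity.CLEAR, True, PresentationType.WARNING),
            # hedged language downgrades a clear action to information
            ("the dose could be halved", ActionSpecificity.CLEAR, False, PresentationType.INFORMATION),
        ],
    )
    def test_decision_procedure(self, text, action, consequence, expected):
        assert classify_statement(_stmt(text, action, consequence)) is expected

    def test_matches_exhaustive_truth_table(self):
        """Hand-enumerated expectation over action x consequence x certainty."""
        texts = {
            Certainty.LOW: "this may matter",
            Certainty.MEDIUM_HIGH: "this is important",
            Certainty.NONE: "take note",
        }
        for action in ActionSpecificity:
            for consequence in (False, True):
                for certainty, text in texts.items():
                    if consequence:
                        expected = PresentationType.WARNING
                    elif action is ActionSpecificity.CLEAR and certainty is Certainty.MEDIUM_HIGH:
                        expected = PresentationType.RECOMMENDATION
                    else:
                        expected = PresentationType.INFORMATION
                    assert classify_statement(_stmt(text, action, consequence)) is expected

    @settings(derandomize=True, max_examples=60)
    @given(
        action=st.sampled_from(list(ActionSpecificity)),
        text=st.sampled_from(["may apply", "is key", "note this"]),
    )
    def test_consequence_flag_never_lowers_severity(self, action, text):
        without = classify_statement(_stmt(text, action, False))
        with_flag = classify_statement(_stmt(text, action, True))
        assert with_flag.severity >= without.severity

    @settings(derandomize=True, max_examples=60)
    @given(
        consequence=st.booleans(),
        text=st.sampled_from(["may apply", "is key", "note this"]),
    )
    def test_raising_action_specificity_never_lowers_severity(self, consequence, text):
        order = [ActionSpecificity.NONE, ActionSpecificity.VAGUE, ActionSpecificity.CLEAR]
        severities = [classify_statement(_stmt(text, a, consequence)).severity for a in order]
        assert severities == sorted(severities)

    def test_empty_lexicon_blocks_recommendations(self):
        empty = CertaintyLexicon(low_terms=frozenset(), high_terms=frozenset())
        stmt = _stmt("the dose is reduced by 50%", ActionSpecificity.CLEAR, False)
        assert classify_statement(stmt, empty) is PresentationType.INFORMATION


class TestClassifyCatalog:
    def test_worked_catalog_distribution(self, worked_catalog):
        assignments, report = classify_catalog(worked_catalog)
        assert report.counts == {
            PresentationType.RECOMMENDATION: 2,
            PresentationType.INFORMATION: 2,
            PresentationType.WARNING: 1,
        }
        assert report.total == 5
        assert sum(report.counts.values()) == len(worked_catalog.rules)

    def test_worked_labels_in_printed_order(self, worked_catalog):
        labels = [classify_rule(r) for r in worked_catalog.rules]
        assert labels == [
            PresentationType.RECOMMENDATION,
            PresentationType.RECOMMENDATION,
            PresentationType.INFORMATION,
            PresentationType.INFORMATION,
            PresentationType.WARNING,
        ]

    def test_multi_consequent_rule_takes_max_severity(self, warfarin):
        assert classify_rule(warfarin) is PresentationType.WARNING

    def test_single_warning_catalog(self, warfarin):
        _, report = classify_catalog(RuleCatalog(rules=[warfarin]))
        assert report.counts[PresentationType.WARNING] == 1
        assert report.percentages[PresentationType.WARNING] == 100

    def test_order_invariance_of_distribution(self, worked_catalog):
        _, fwd = classify_catalog(worked_catalog)
        reversed_cat = RuleCatalog(rules=list(reversed(worked_catalog.rules)))
        _, rev = classify_catalog(reversed_cat)
        assert fwd.counts == rev.counts and fwd.percentages == rev.percentages

    def test_empty_catalog_is_an_error(self):
        with pytest.raises(EmptyCatalogError):
            classify_catalog(RuleCatalog(rules=[]))

    @pytest.mark.parametrize("seed,n", [(7, 200), (11, 40)])
    def test_recovers_planted_labels_exactly(self, seed, n):
        cat = gen_rule_catalog(GeneratorSpec(seed=seed, n=n))
        assignments, _ = classify_catalog(cat)
        planted = cat.metadata["ground_truth"]["presentation"]
        assert {rid: t.value for rid, t in assignments.items()} == planted
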
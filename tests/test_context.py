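"""Assertion classification: triggers, scopes, terminations, pseudo-triggers."""

import random

import pytest

from housenlp.context import (
    AssertionStatus,
    RuleFileError,
    assert_corpus,
    classify_context,
    load_context_rules,
)
from housenlp.matcher import match_concepts
from housenlp.segmenter import ClinicalNote, segment

RULE_HEADER = (
    "rule_id\ttrigger\tdimension\tvalue\tdirection\tmax_scope_tokens\tenabled\n"
)


def write_rules(tmp_path, rows, name="rules.tsv"):
    path = tmp_path / name
    path.write_text(RULE_HEADER + "".join("\t".join(r) + "\n" for r in rows), encoding="utf-8")
    return path


def asserted(text, lexicon, rules, note_id="n"):
    """Segment, match and classify one note; returns (sentence, mention, status) triples."""
    note = ClinicalNote(note_id, text)
    out = []
    for sentence in segment(note):
        for mention in match_concepts(sentence, lexicon):
            out.append((sentence, mention, classify_context(mention, sentence, rules)))
    return out


class TestLoadContextRules:
    def test_default_file_ships_pruned_test_result_triggers_disabled(self, rules):
        disabled_ids = {r.rule_id for r in rules.disabled}
        assert "did_not_demonstrate" in disabled_ids
        assert all(not r.enabled for r in rules.disabled)
        assert all(r.enabled for r in rules)

    def test_minimal_two_rule_file(self, tmp_path):
        path = write_rules(
            tmp_path,
            [
                ("r1", "denies", "negation", "negated", "forward", "", "true"),
                ("r2", "history of", "temporality", "historical", "forward", "", "true"),
            ],
        )
        loaded = load_context_rules(path)
        assert [r.rule_id for r in loaded] == ["r1", "r2"]
        assert loaded.disabled == []

    def test_duplicate_rule_id_is_fatal(self, tmp_path):
        path = write_rules(
            tmp_path,
            [
                ("r1", "denies", "negation", "negated", "forward", "", "true"),
                ("r1", "no", "negation", "negated", "forward", "", "true"),
            ],
        )
        with pytest.raises(RuleFileError, match="duplicate rule_id"):
            load_context_rules(path)

    def test_non_compiling_trigger_names_the_rule(self, tmp_path):
        path = write_rules(
            tmp_path, [("bad", "den(ies", "negation", "negated", "forward", "", "true")]
        )
        with pytest.raises(RuleFileError, match="bad"):
            load_context_rules(path)

    def test_inconsistent_dimension_value_pairing_is_fatal(self, tmp_path):
        path = write_rules(
            tmp_path, [("r1", "denies", "negation", "historical", "forward", "", "true")]
        )
        with pytest.raises(RuleFileError, match="inconsistent"):
            load_context_rules(path)


class TestClassifyContext:
    def test_iv_abx_sentence_reproduces_scope_confusion(self, lexicon, rules):
        # the documented limitation: "not" wrongly negates "homelessness"
        text = (
            "Patient is not safe candidate for home IV abx therapy "
            "given active IVDA and homelessness"
        )
        ((_, mention, status),) = asserted(text, lexicon, rules)
        assert mention.matched_text == "homelessness"
        assert status.negated is True
        assert "neg_not" in status.firing_rules

    def test_no_trigger_yields_default_status(self, lexicon, rules):
        ((_, _, status),) = asserted("Patient is homeless", lexicon, rules)
        assert status == AssertionStatus(negated=False, historical=False,
                                         experiencer="patient", firing_rules=())

    def test_termination_term_ends_forward_negation_scope(self, lexicon, rules):
        text = "Patient denies being homeless but her brother is homeless"
        results = asserted(text, lexicon, rules)
        assert len(results) == 2
        (_, _, first), (_, _, second) = results
        assert first.negated is True
        assert second.negated is False  # "but" terminates the denies-scope
        assert second.experiencer == "other"  # "brother" claims the second mention

    def test_family_member_mention_gets_other_experiencer(self, lexicon, rules):
        ((_, _, status),) = asserted(
            "Patient reports her mother is experiencing homelessness", lexicon, rules
        )
        assert status.experiencer == "other" and status.negated is False

    def test_historical_dimension(self, lexicon, rules):
        ((_, _, status),) = asserted("Patient has a history of homelessness.", lexicon, rules)
        assert status.historical is True and status.negated is False

    def test_pseudo_trigger_blocks_real_trigger(self, lexicon, tmp_path):
        path = write_rules(
            tmp_path,
            [
                ("neg_no", "no", "negation", "negated", "forward", "", "true"),
                ("pseudo", "no increase", "negation", "none", "forward", "", "true"),
            ],
        )
        pseudo_rules = load_context_rules(path)
        ((_, _, status),) = asserted(
            "There was no increase in homelessness outreach visits", lexicon, pseudo_rules
        )
        assert status.negated is False

    def test_max_scope_tokens_clips_forward_reach(self, lexicon, tmp_path):
        path = write_rules(
            tmp_path, [("neg", "denies", "negation", "negated", "forward", "2", "true")]
        )
        short_rules = load_context_rules(path)
        ((_, _, near),) = asserted("Patient denies being homeless", lexicon, short_rules)
        assert near.negated is True
        ((_, _, far),) = asserted(
            "Patient denies chest pain radiating and is homeless", lexicon, short_rules
        )
        assert far.negated is False

    def test_scope_never_crosses_sentence_boundary(self, lexicon, rules):
        text = "Patient denies chest pain. Patient is homeless."
        ((_, mention, status),) = asserted(text, lexicon, rules)
        assert mention.matched_text == "homeless"
        assert status.negated is False

    def test_trigger_inside_mention_does_not_fire(self, lexicon, rules):
        # "no fixed abode" contains the trigger word "no"
        ((_, mention, status),) = asserted("Patient has no fixed abode", lexicon, rules)
        assert mention.matched_text == "no fixed abode"
        assert status.negated is False

    def test_mention_outside_sentence_is_an_error(self, lexicon, rules):
        note = ClinicalNote("n", "First sentence. Patient is homeless.")
        first, second = segment(note)
        (mention,) = match_concepts(second, lexicon)
        with pytest.raises(ValueError, match="outside"):
            classify_context(mention, first, rules)

    def test_rule_order_does_not_matter(self, lexicon, rules):
        text = "Patient denies being homeless but her brother is homeless"
        baseline = [s for _, _, s in asserted(text, lexicon, rules)]
        shuffled = list(rules)
        random.Random(99).shuffle(shuffled)
        assert [s for _, _, s in asserted(text, lexicon, shuffled)] == baseline

    def test_disabling_all_rules_gives_defaults_everywhere(self, lexicon, rules):
        text = "Patient denies homelessness; her brother has a history of cold exposure."
        for _, _, status in asserted(text, lexicon, []):
            assert status == AssertionStatus()


class TestAssertCorpus:
    def test_empty_input_yields_empty_output(self, rules):
        assert assert_corpus({}, {}, rules) == []

    def test_matches_per_mention_invocation(self, lexicon, rules):
        note = ClinicalNote("n", "Patient denies being homeless. Sister is unhoused.")
        sentences = segment(note)
        mentions = [m for s in sentences for m in match_concepts(s, lexicon)]
        bulk = assert_corpus({"n": mentions}, {"n": sentences}, rules)
        solo = [
            classify_context(m, sentences[m.sentence_index], rules) for m in mentions
        ]
        assert [am.status for am in bulk] == solo
        assert [am.mention for am in bulk] == mentions

    def test_missing_sentences_is_an_error(self, lexicon, rules):
        note = ClinicalNote("n", "Patient is homeless.")
        sentences = segment(note)
        mentions = [m for s in sentences for m in match_concepts(s, lexicon)]
        with pytest.raises(ValueError, match="no sentences"):
            assert_corpus({"n": mentions}, {}, rules)

    def test_scope_containment_within_sentences(self, lexicon, rules):
        note = ClinicalNote(
            "n", "No concerns today. Patient is homeless.\nDenies cold exposure."
        )
        sentences = segment(note)
        mentions = [m for s in sentences for m in match_concepts(s, lexicon)]
        for am in assert_corpus({"n": mentions}, {"n": sentences}, rules):
            s = sentences[am.mention.sentence_index]
            assert s.start <= am.mention.start and am.mention.end <= s.end
        # the homeless mention sits in a different sentence from both triggers
        statuses = {
            am.mention.matched_text: am.status.negated
            for am in assert_corpus({"n": mentions}, {"n": sentences}, rules)
        }
        assert statuses["homeless"] is False
        assert statuses["cold exposure"] is True
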
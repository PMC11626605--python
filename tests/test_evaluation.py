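"""Evaluation: confusion matrices, undefined metrics, error bucketing."""

import random

import pytest

from housenlp.classify import annotate_note
from housenlp.evaluation import (
    ErrorCase,
    EvalResult,
    GoldLabel,
    GoldMention,
    bucket_errors,
    collect_note_errors,
    evaluate_hits,
    evaluate_notes,
)
from housenlp.lexicon import ConceptCategory
from housenlp.segmenter import ClinicalNote, Sentence


def sent(text, note_id="n", index=0):
    return Sentence(note_id=note_id, index=index, start=0, end=len(text), text=text)


class TestEvaluateNotes:
    def test_perfect_classifier_on_toy_corpus(self):
        gold = [GoldLabel(f"n{i}", "positive") for i in range(2)] + [
            GoldLabel(f"n{i}", "negative") for i in range(2, 4)
        ]
        preds = [(g.note_id, g.label) for g in gold]
        result = evaluate_notes(preds, gold)
        assert (result.tp, result.fp, result.tn, result.fn) == (2, 0, 2, 0)
        assert result.precision == 1.0 and result.recall == 1.0

    def test_missed_positive_counts_as_fn(self):
        result = evaluate_notes(
            [("a", "negative")], [GoldLabel("a", "positive")]
        )
        assert (result.tp, result.fp, result.tn, result.fn) == (0, 0, 0, 1)

    def test_unmatched_ids_error_lists_them(self):
        with pytest.raises(ValueError, match="b.*c"):
            evaluate_notes([("a", "positive"), ("b", "negative")],
                           [GoldLabel("a", "positive"), GoldLabel("c", "negative")])

    def test_confusion_conservation(self):
        rng = random.Random(3)
        gold = [GoldLabel(f"n{i}", rng.choice(["positive", "negative"])) for i in range(50)]
        preds = [(g.note_id, rng.choice(["positive", "negative"])) for g in gold]
        result = evaluate_notes(preds, gold)
        assert result.n == 50

    def test_prediction_swap_symmetry(self):
        rng = random.Random(4)
        gold = [GoldLabel(f"n{i}", rng.choice(["positive", "negative"])) for i in range(60)]
        preds = [(g.note_id, rng.choice(["positive", "negative"])) for g in gold]
        flipped = [
            (nid, "negative" if lab == "positive" else "positive") for nid, lab in preds
        ]
        a, b = evaluate_notes(preds, gold), evaluate_notes(flipped, gold)
        assert (a.tp, a.fp, a.tn, a.fn) == (b.fn, b.tn, b.fp, b.tp)

    def test_self_evaluation_is_perfect(self):
        rng = random.Random(5)
        gold = [GoldLabel(f"n{i}", rng.choice(["positive", "negative"])) for i in range(40)]
        result = evaluate_notes([(g.note_id, g.label) for g in gold], gold)
        assert result.precision in (1.0, None) and result.fn == 0 and result.fp == 0


class TestUndefinedMetrics:
    def test_precision_only_review_reports_recall_as_na(self):
        # hits reviewed for correctness: gold contains only positives that the
        # system predicted; recall is undefined, never 0
        result = EvalResult(tp=98, fp=9, tn=0, fn=0, precision_only=True)
        assert result.recall is None
        assert "recall=N/A" in result.summary()
        assert result.precision == pytest.approx(98 / 107)

    def test_empty_evaluation_has_no_defined_ratios(self):
        result = evaluate_notes([], [])
        assert result.precision is None and result.recall is None and result.f1 is None


class TestEvaluateHits:
    def test_wrongly_negated_prediction_is_hit_level_fn(self, lexicon, rules):
        text = ("Patient is not safe candidate for home IV abx therapy "
                "given active IVDA and homelessness")
        ann = annotate_note(ClinicalNote("n", text), lexicon, rules)
        (am,) = ann.asserted_mentions
        assert am.status.negated  # precondition: the scope confusion happened
        gold = {
            "n": [GoldMention(am.mention.start, am.mention.end,
                              ConceptCategory.HOMELESS, positive=True)]
        }
        result = evaluate_hits(list(ann.asserted_mentions), gold)
        assert (result.tp, result.fp, result.fn) == (0, 0, 1)

    def test_exact_agreement_is_tp(self, lexicon, rules):
        ann = annotate_note(ClinicalNote("n", "Patient is homeless."), lexicon, rules)
        (am,) = ann.asserted_mentions
        gold = {"n": [GoldMention(am.mention.start, am.mention.end,
                                  ConceptCategory.HOMELESS, positive=True)]}
        result = evaluate_hits(list(ann.asserted_mentions), gold)
        assert (result.tp, result.fp, result.fn) == (1, 0, 0)

    def test_unmatched_positive_prediction_is_fp(self, lexicon, rules):
        ann = annotate_note(ClinicalNote("n", "Patient is homeless."), lexicon, rules)
        result = evaluate_hits(list(ann.asserted_mentions), {"n": []})
        assert (result.tp, result.fp, result.fn) == (0, 1, 0)

    def test_partial_overlap_with_matching_concept_aligns(self, lexicon, rules):
        ann = annotate_note(ClinicalNote("n", "slept at the homeless shelter"), lexicon, rules)
        (am,) = ann.asserted_mentions
        gold = {"n": [GoldMention(am.mention.start, am.mention.start + 3,
                                  ConceptCategory.EMERGENCY_HOUSING, positive=True)]}
        result = evaluate_hits(list(ann.asserted_mentions), gold)
        assert result.tp == 1

    def test_missed_gold_mention_is_fn(self):
        gold = {"n": [GoldMention(0, 8, ConceptCategory.HOMELESS, positive=True)]}
        result = evaluate_hits([], gold)
        assert (result.tp, result.fp, result.fn) == (0, 0, 1)


class TestBucketErrors:
    def test_resource_list_fp(self):
        err = ErrorCase(
            note_id="n", kind="fp",
            sentence=sent("Homeless Veterans Center: 555-0142"),
            section_header="Patient Education:",
        )
        buckets = bucket_errors([err])
        assert buckets["resource_list_fp"] == [err]

    def test_third_party_fp(self):
        err = ErrorCase(
            note_id="n", kind="fp",
            sentence=sent("found a homeless person sleeping in her bathroom"),
        )
        assert bucket_errors([err])["third_party_fp"] == [err]

    def test_family_member_fp(self):
        err = ErrorCase(
            note_id="n", kind="fp",
            sentence=sent("patient's brother is homeless"),
        )
        assert bucket_errors([err])["family_member_fp"] == [err]

    def test_negation_scope_fn(self):
        err = ErrorCase(
            note_id="n", kind="fn",
            sentence=sent("Patient is not safe candidate for home IV abx therapy "
                          "given active IVDA and homelessness"),
        )
        assert bucket_errors([err])["negation_scope_fn"] == [err]

    def test_unclassifiable_errors_land_in_other(self):
        fp = ErrorCase(note_id="n", kind="fp", sentence=sent("housing conference flyer"))
        fn = ErrorCase(note_id="n", kind="fn", sentence=sent("patient lost the apartment"))
        buckets = bucket_errors([fp, fn])
        assert buckets["other"] == [fp, fn]

    def test_collect_note_errors_end_to_end(self, lexicon, rules):
        text = (
            "CHIEF COMPLAINT: Laceration\n\nPATIENT EDUCATION:\n"
            "Homeless Veterans Center: 555-0142\n"
        )
        ann = annotate_note(ClinicalNote("n", text), lexicon, rules)
        assert ann.label == "positive"  # the designed resource-list FP
        errors = collect_note_errors([ann], [GoldLabel("n", "negative")])
        buckets = bucket_errors(errors)
        assert len(buckets["resource_list_fp"]) == 1
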
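"""Scoring against gold labels, at note level and at individual-hit level,
plus bucketing of errors into the recurring failure modes of rule-based
housing extraction (resource lists, third-party mentions, family members,
negation-scope confusions).

Undefined ratios are reported as ``None`` / "N/A", never coerced to 0: in a
precision-only review setting (hits reviewed for correctness, no gold
negatives) recall simply does not exist.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .context import AssertedMention, is_positive_hit
from .lexicon import ConceptCategory
from .segmenter import Sentence

__all__ = [
    "GoldLabel",
    "GoldMention",
    "EvalResult",
    "ErrorCase",
    "evaluate_notes",
    "evaluate_hits",
    "bucket_errors",
    "collect_note_errors",
    "read_gold_csv",
]

POSITIVE = "positive"
NEGATIVE = "negative"

ERROR_BUCKETS = (
    "resource_list_fp",
    "third_party_fp",
    "family_member_fp",
    "negation_scope_fn",
    "other",
)


@dataclass(frozen=True)
class GoldMention:
    start: int
    end: int
    concept: ConceptCategory
    positive: bool  # True = affirmed patient mention


@dataclass(frozen=True)
class GoldLabel:
    note_id: str
    label: str  # positive | negative
    gold_mentions: tuple[GoldMention, ...] = ()


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts with lazily-derived, possibly-undefined ratios.

    ``precision_only=True`` marks a review-style evaluation where the gold
    standard consists only of system hits reviewed for correctness: false
    negatives are unobservable, so recall is undefined by construction
    (reported "N/A", never 0).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    level: str = "note"  # note | hit
    precision_only: bool = False

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def precision(self) -> Optional[float]:
        denom = self.tp + self.fp
        return self.tp / denom if denom else None

    @property
    def recall(self) -> Optional[float]:
        if self.precision_only:
            return None
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def f1(self) -> Optional[float]:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return None
        return 2 * p * r / (p + r)

    def summary(self) -> str:
        def fmt(x: Optional[float]) -> str:
            return "N/A" if x is None else f"{x:.4f}"

        return (
            f"{self.level}-level evaluation (n={self.n})\n"
            f"  TP={self.tp}  FP={self.fp}  TN={self.tn}  FN={self.fn}\n"
            f"  precision={fmt(self.precision)}  recall={fmt(self.recall)}"
            f"  F1={fmt(self.f1)}"
        )


def read_gold_csv(path: str | Path) -> list[GoldLabel]:
    """Read a note-level gold file: CSV with columns note_id,label."""
    gold: list[GoldLabel] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"note_id", "label"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: gold CSV needs columns note_id,label")
        for row in reader:
            label = row["label"].strip().lower()
            if label not in (POSITIVE, NEGATIVE):
                raise ValueError(f"{path}: bad label {row['label']!r} for {row['note_id']!r}")
            gold.append(GoldLabel(note_id=row["note_id"], label=label))
    return gold


def evaluate_notes(
    predictions: Sequence[tuple[str, str]], gold: Sequence[GoldLabel]
) -> EvalResult:
    """Note-level confusion matrix of predicted vs gold labels.

    Every prediction must have a gold label and vice versa; mismatched ids
    abort with the offending ids listed.
    """
    pred_map = dict(predictions)
    if len(pred_map) != len(predictions):
        raise ValueError("duplicate note_id among predictions")
    gold_map = {g.note_id: g.label for g in gold}
    if len(gold_map) != len(gold):
        raise ValueError("duplicate note_id among gold labels")
    missing_gold = sorted(set(pred_map) - set(gold_map))
    missing_pred = sorted(set(gold_map) - set(pred_map))
    if missing_gold or missing_pred:
        raise ValueError(
            f"unmatched note ids: no gold for {missing_gold}, no prediction for {missing_pred}"
        )
    tp = fp = tn = fn = 0
    for note_id, pred in pred_map.items():
        g = gold_map[note_id]
        if pred == POSITIVE and g == POSITIVE:
            tp += 1
        elif pred == POSITIVE and g == NEGATIVE:
            fp += 1
        elif pred == NEGATIVE and g == NEGATIVE:
            tn += 1
        else:
            fn += 1
    return EvalResult(tp=tp, fp=fp, tn=tn, fn=fn, level="note")


def evaluate_hits(
    predicted_hits: Sequence[AssertedMention],
    gold_mentions: dict[str, Sequence[GoldMention]],
    precision_only: bool = False,
) -> EvalResult:
    """Hit-level confusion counts using span-overlap matching.

    A predicted and a gold mention align when they share a note, overlap by
    at least one character, and agree on concept. The statuses then decide
    the cell: an aligned pair where the system says positive and the gold
    annotation says positive is a TP; a prediction wrongly negated (or
    attributed to another experiencer) against an affirmed gold mention is
    a hit-level FN; a positive prediction with no affirmed gold counterpart
    is an FP. When several predictions align to one gold mention only the
    leftmost is scored; the rest are ignored.
    """
    tp = fp = tn = fn = 0
    matched_preds: set[int] = set()
    preds_by_note: dict[str, list[tuple[int, AssertedMention]]] = {}
    for i, am in enumerate(predicted_hits):
        preds_by_note.setdefault(am.mention.note_id, []).append((i, am))
    for note_id, golds in gold_mentions.items():
        preds = sorted(
            preds_by_note.get(note_id, []), key=lambda item: item[1].mention.start
        )
        for g in golds:
            aligned = [
                (i, am)
                for i, am in preds
                if i not in matched_preds
                and am.mention.concept == g.concept
                and am.mention.start < g.end
                and g.start < am.mention.end
            ]
            if not aligned:
                if g.positive:
                    fn += 1  # system produced no hit where one was annotated
                else:
                    tn += 1
                continue
            i, am = aligned[0]
            matched_preds.add(i)
            for j, _ in aligned[1:]:
                matched_preds.add(j)  # extras ignored, not penalized
            pred_positive = is_positive_hit(am)
            if pred_positive and g.positive:
                tp += 1
            elif pred_positive and not g.positive:
                fp += 1
            elif not pred_positive and g.positive:
                fn += 1
            else:
                tn += 1
    for i, am in enumerate(predicted_hits):
        if i not in matched_preds and am.mention.note_id in gold_mentions:
            if is_positive_hit(am):
                fp += 1
            else:
                tn += 1
    return EvalResult(tp=tp, fp=fp, tn=tn, fn=fn, level="hit", precision_only=precision_only)


@dataclass(frozen=True)
class ErrorCase:
    """One misclassification with the context needed to bucket it."""

    note_id: str
    kind: str  # "fp" | "fn"
    sentence: Sentence
    section_header: Optional[str] = None
    firing_rules: tuple[str, ...] = ()


_RESOURCE_HEADER = re.compile(
    r"(patient\s+education|resources?|referrals?|community\s+services)", re.IGNORECASE
)
_THIRD_PARTY = re.compile(
    r"\b(?:an?|another|the)\s+(?:\w+\s+){0,2}?(?:person|individual|man|woman|veteran|people)s?\b",
    re.IGNORECASE,
)
_EXPERIENCER_WORD = re.compile(
    r"\b(brother|sister|mother|father|aunt|uncle|grandmother|grandfather|wife|"
    r"husband|son|daughter|cousin|roommate|neighbor|family\s+members?)\b",
    re.IGNORECASE,
)
_NEGATION_WORD = re.compile(
    r"\b(no|not|denies|denied|without|never|unlikely)\b", re.IGNORECASE
)


def bucket_errors(errors: Sequence[ErrorCase]) -> dict[str, list[ErrorCase]]:
    """Assign each error to a named failure bucket by sentence features.

    False positives under resource-list section headers go to
    ``resource_list_fp``; those mentioning another experiencer word to
    ``family_member_fp``; those describing a generic third person
    ("a homeless person ...") to ``third_party_fp``. False negatives whose
    sentence carries a negation word go to ``negation_scope_fn``; anything
    else lands in ``other``.
    """
    buckets: dict[str, list[ErrorCase]] = {b: [] for b in ERROR_BUCKETS}
    for err in errors:
        text = err.sentence.text
        if err.kind == "fp":
            if err.section_header and _RESOURCE_HEADER.search(err.section_header):
                buckets["resource_list_fp"].append(err)
            elif _EXPERIENCER_WORD.search(text):
                buckets["family_member_fp"].append(err)
            elif _THIRD_PARTY.search(text):
                buckets["third_party_fp"].append(err)
            else:
                buckets["other"].append(err)
        elif err.kind == "fn":
            if _NEGATION_WORD.search(text):
                buckets["negation_scope_fn"].append(err)
            else:
                buckets["other"].append(err)
        else:
            raise ValueError(f"unknown error kind {err.kind!r}")
    return buckets


def collect_note_errors(annotated_notes, gold: Sequence[GoldLabel]) -> list[ErrorCase]:
    """Turn note-level disagreements into bucketable ErrorCases.

    For a false-positive note the sentence of its first positive hit is the
    evidence; for a false-negative note, the sentence of its first
    (suppressed) mention. The nearest preceding header-like sentence
    (ending with ':') is attached for resource-list detection.
    """
    gold_map = {g.note_id: g.label for g in gold}
    errors: list[ErrorCase] = []
    for annotated in annotated_notes:
        g = gold_map.get(annotated.note.note_id)
        if g is None or annotated.label == g:
            continue
        kind = "fp" if annotated.label == POSITIVE else "fn"
        if kind == "fp":
            culprits = [am for am in annotated.asserted_mentions if is_positive_hit(am)]
        else:
            culprits = list(annotated.asserted_mentions)
        if not culprits:
            continue  # fn with no mentions at all: nothing to show
        am = culprits[0]
        sentence = annotated.sentences[am.mention.sentence_index]
        header = None
        for s in annotated.sentences[: am.mention.sentence_index + 1]:
            if s.text.rstrip().endswith(":"):
                header = s.text
        errors.append(
            ErrorCase(
                note_id=annotated.note.note_id,
                kind=kind,
                sentence=sentence,
                section_header=header,
                firing_rules=am.status.firing_rules,
            )
        )
    return errors
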
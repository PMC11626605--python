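"""Note-level labels and corpus-level concept distributions.

The labelling rule is deliberately simple: a note is *positive* for housing
issues iff at least one of its asserted mentions is a positive hit
(affirmed, about the patient). A note with no mentions, or whose mentions
are all negated or attributed to someone else, is *negative*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .context import AssertedMention, RuleList, classify_context, is_positive_hit
from .lexicon import CompiledLexicon, ConceptCategory
from .matcher import match_concepts
from .segmenter import ClinicalNote, Sentence, segment

__all__ = [
    "AnnotatedNote",
    "ConceptDistribution",
    "classify_note",
    "annotate_note",
    "concept_distribution",
    "patient_rollup",
]

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class AnnotatedNote:
    """A note with its sentences, asserted mentions, and derived label."""

    note: ClinicalNote
    sentences: tuple[Sentence, ...]
    asserted_mentions: tuple[AssertedMention, ...]
    label: str  # POSITIVE | NEGATIVE

    @property
    def n_positive_hits(self) -> int:
        return sum(1 for am in self.asserted_mentions if is_positive_hit(am))


def classify_note(
    asserted_mentions: Sequence[AssertedMention],
    historical_counts_positive: bool = True,
) -> str:
    """positive iff any hit is affirmed and about the patient; else negative."""
    note_ids = {am.mention.note_id for am in asserted_mentions}
    if len(note_ids) > 1:
        raise ValueError(f"mentions from multiple notes: {sorted(note_ids)}")
    if any(is_positive_hit(am, historical_counts_positive) for am in asserted_mentions):
        return POSITIVE
    return NEGATIVE


def annotate_note(
    note: ClinicalNote,
    lexicon: CompiledLexicon,
    rules: RuleList | Sequence,
    historical_counts_positive: bool = True,
) -> AnnotatedNote:
    """Run segment → match → assert → label for a single note."""
    sentences = segment(note)
    asserted: list[AssertedMention] = []
    for sentence in sentences:
        for mention in match_concepts(sentence, lexicon):
            asserted.append(
                AssertedMention(mention, classify_context(mention, sentence, rules))
            )
    label = classify_note(asserted, historical_counts_positive) if asserted else NEGATIVE
    return AnnotatedNote(
        note=note,
        sentences=tuple(sentences),
        asserted_mentions=tuple(asserted),
        label=label,
    )


@dataclass(frozen=True)
class ConceptDistribution:
    """Mention counts per concept over a corpus, on a declared basis."""

    counts: dict[ConceptCategory, int]
    basis: str  # "all_hits" | "positive_hits"

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def concept_distribution(
    notes: Sequence[AnnotatedNote], basis: str = "positive_hits"
) -> ConceptDistribution:
    """Count asserted mentions per concept; basis filters to positive hits."""
    if basis not in ("all_hits", "positive_hits"):
        raise ValueError(f"unknown basis {basis!r}")
    counts = {concept: 0 for concept in ConceptCategory}
    for annotated in notes:
        for am in annotated.asserted_mentions:
            if basis == "positive_hits" and not is_positive_hit(am):
                continue
            counts[am.mention.concept] += 1
    return ConceptDistribution(counts=counts, basis=basis)


def patient_rollup(
    notes: Sequence[AnnotatedNote], patient_of: dict[str, str]
) -> dict[str, str]:
    """Convenience patient-level rollup: any positive note makes the patient positive."""
    labels: dict[str, str] = {}
    for annotated in notes:
        patient = patient_of[annotated.note.note_id]
        if annotated.label == POSITIVE:
            labels[patient] = POSITIVE
        else:
            labels.setdefault(patient, NEGATIVE)
    return labels
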
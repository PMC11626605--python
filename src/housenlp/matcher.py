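"""Dictionary matching: find lexicon hits in sentences and emit mentions.

Matching is sentence-local (a pattern never crosses a sentence boundary)
and deterministic. Overlap resolution follows the conventional dictionary
rule: leftmost match first, longest match at a position wins, ties at the
same span go to the earlier lexicon entry, and any candidate overlapping an
accepted match is suppressed — so "homeless shelter" yields one
emergency-housing mention, not an extra homeless mention inside it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .lexicon import CompiledLexicon, ConceptCategory
from .segmenter import ClinicalNote, Sentence, segment

__all__ = ["Mention", "match_concepts", "match_corpus"]


@dataclass(frozen=True)
class Mention:
    """One lexicon hit with note-relative character offsets."""

    note_id: str
    sentence_index: int
    concept: ConceptCategory
    matched_text: str
    start: int  # note-relative, 0-based half-open
    end: int
    entry_id: int


def match_concepts(sentence: Sentence, lexicon: CompiledLexicon) -> list[Mention]:
    """All maximal, non-overlapping lexicon matches in one sentence."""
    candidates: list[tuple[int, int, int, int]] = []
    for entry in lexicon.entries:
        for m in entry.regex.finditer(sentence.text):
            if m.end() > m.start():
                candidates.append((m.start(), -(m.end() - m.start()), entry.entry_id, m.end()))
    candidates.sort()
    mentions: list[Mention] = []
    last_end = 0
    for start, _neg_len, entry_id, end in candidates:
        if start < last_end:
            continue
        entry = lexicon.entries[entry_id]
        mentions.append(
            Mention(
                note_id=sentence.note_id,
                sentence_index=sentence.index,
                concept=entry.concept,
                matched_text=sentence.text[start:end],
                start=sentence.start + start,
                end=sentence.start + end,
                entry_id=entry_id,
            )
        )
        last_end = end
    return mentions


def match_corpus(
    notes: list[ClinicalNote], lexicon: CompiledLexicon
) -> dict[str, list[Mention]]:
    """Match every note, returning mentions grouped by note id.

    Order is (note order, sentence order, offset order). Duplicate note ids
    are rejected before any matching happens.
    """
    seen: set[str] = set()
    for note in notes:
        if note.note_id in seen:
            raise ValueError(f"duplicate note_id {note.note_id!r}")
        seen.add(note.note_id)
    out: dict[str, list[Mention]] = {}
    for note in notes:
        mentions: list[Mention] = []
        for sentence in segment(note):
            mentions.extend(match_concepts(sentence, lexicon))
        out[note.note_id] = mentions
    return out
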
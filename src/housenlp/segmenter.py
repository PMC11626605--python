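"""Sentence segmentation with exact character offsets.

Assertion scope in this pipeline is sentence-bounded — a negation trigger
can never reach a concept in a neighbouring sentence — so the segmenter is
the piece that fixes every downstream contextual window. It is a
deterministic rule-based splitter:

* every line break is a hard boundary, which isolates section headers
  ("Patient Education:") and list items on their own lines;
* within a line, sentences end at ``.``, ``!`` or ``?`` followed by
  whitespace or end-of-line, except after protected abbreviations
  ("Dr.", "pt.", "b.i.d.") and inside decimal numbers;
* spans are 0-based half-open ``[start, end)`` in code points, include the
  terminal punctuation, and exclude surrounding whitespace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = ["ClinicalNote", "Sentence", "segment"]


@dataclass(frozen=True)
class ClinicalNote:
    """A clinical document: an opaque id plus its full text."""

    note_id: str
    text: str
    meta: Optional[dict] = field(default=None, compare=False)


@dataclass(frozen=True)
class Sentence:
    """A sentence span of a note; ``text == note.text[start:end]``."""

    note_id: str
    index: int
    start: int
    end: int
    text: str


# tokens after which a period never ends a sentence (compared lowercase,
# without the final period)
_ABBREVIATIONS = {
    "dr", "mr", "mrs", "ms", "prof", "st",
    "pt", "hx", "dx", "tx", "fx", "sx",
    "vs", "etc", "approx", "no",
    "e.g", "i.e", "a.m", "p.m",
    "b.i.d", "t.i.d", "q.i.d", "p.r.n", "p.o", "q.d",
}

_TERMINATORS = ".!?"


def _is_protected_period(text: str, i: int, line_start: int) -> bool:
    """True when the period at *i* must not end a sentence."""
    if text[i] != ".":
        return False
    # decimal number: digit on both sides
    if 0 < i < len(text) - 1 and text[i - 1].isdigit() and text[i + 1].isdigit():
        return True
    j = i
    while j > line_start and not text[j - 1].isspace():
        j -= 1
    token = text[j:i].lower()
    return token in _ABBREVIATIONS


def _emit(note: ClinicalNote, spans: list[tuple[int, int]], seg_start: int, seg_end: int) -> None:
    """Trim whitespace off [seg_start, seg_end) and record it if non-empty."""
    text = note.text
    start, end = seg_start, seg_end
    while start < end and text[start].isspace():
        start += 1
    while end > start and text[end - 1].isspace():
        end -= 1
    if start < end:
        spans.append((start, end))


def segment(note: ClinicalNote) -> list[Sentence]:
    """Split a note into ordered, non-overlapping sentences.

    Empty text yields an empty list; text without terminal punctuation
    yields a single sentence spanning the trimmed text.
    """
    text = note.text
    spans: list[tuple[int, int]] = []
    n = len(text)
    i = 0
    line_start = 0
    seg_start = 0
    while i < n:
        ch = text[i]
        if ch == "\n":
            _emit(note, spans, seg_start, i)
            i += 1
            line_start = i
            seg_start = i
            continue
        if ch in _TERMINATORS:
            # absorb a run of terminators ("?!", "...")
            j = i
            while j + 1 < n and text[j + 1] in _TERMINATORS:
                j += 1
            followed_ok = j + 1 >= n or text[j + 1].isspace()
            if followed_ok and not _is_protected_period(text, i, line_start):
                _emit(note, spans, seg_start, j + 1)
                seg_start = j + 1
            i = j + 1
            continue
        i += 1
    _emit(note, spans, seg_start, n)
    return [
        Sentence(note_id=note.note_id, index=k, start=s, end=e, text=text[s:e])
        for k, (s, e) in enumerate(spans)
    ]
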
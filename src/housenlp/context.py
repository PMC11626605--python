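"""ConText-style assertion classification for matched mentions.

Each mention gets an assertion status along three independent dimensions:
negation ("denies being homeless"), temporality ("history of
homelessness"), and experiencer ("her brother is homeless"). A trigger term
found in the mention's sentence projects a directional scope — forward from
the trigger to the end of the sentence, backward to its start — clipped by
termination terms ("but", "however") and, optionally, by a token budget.
Scope never crosses a sentence boundary: the document is segmented first
precisely so that triggers cannot act on concepts in neighbouring
sentences.

Two rule refinements matter for housing concepts. Pseudo-triggers
(``value = none``) block a real trigger they overlap, so "no increase" does
not negate what follows. And test-result negations such as "did not
demonstrate" ship disabled — housing issues are not findings a patient
tests positive or negative for — while remaining in the rule file's audit
list so the pruning is visible.

The default status (no rule fires) is not-negated, not-historical,
experiencer=patient. A *positive hit* is a mention that is not negated and
belongs to the patient; that predicate drives note-level classification.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .lexicon import LexiconError, compile_pattern
from .matcher import Mention
from .segmenter import Sentence

__all__ = [
    "ContextRule",
    "AssertionStatus",
    "AssertedMention",
    "RuleFileError",
    "RuleList",
    "load_context_rules",
    "default_rules_path",
    "default_rules",
    "classify_context",
    "assert_corpus",
    "is_positive_hit",
]

DIMENSIONS = ("negation", "temporality", "experiencer", "termination")
_DIMENSION_VALUES = {
    "negation": {"negated", "none"},
    "temporality": {"historical", "none"},
    "experiencer": {"other_experiencer", "none"},
    "termination": {"terminate"},
}
_DIRECTIONS = ("forward", "backward", "bidirectional")


class RuleFileError(ValueError):
    """Raised for malformed context-rule files."""


@dataclass(frozen=True)
class ContextRule:
    """One trigger row: pattern, dimension, value, direction, scope bound."""

    rule_id: str
    trigger: str
    dimension: str
    value: str
    direction: str = "forward"
    max_scope_tokens: Optional[int] = None  # None = unbounded within sentence
    enabled: bool = True
    regex: re.Pattern[str] = field(repr=False, compare=False, default=None)  # type: ignore[assignment]

    @property
    def is_pseudo(self) -> bool:
        return self.value == "none"

    @property
    def is_termination(self) -> bool:
        return self.dimension == "termination"


class RuleList(list):
    """Enabled rules, with the pruned (disabled) rules kept for audit."""

    def __init__(self, enabled: Iterable[ContextRule], disabled: Iterable[ContextRule] = ()):
        super().__init__(enabled)
        self.disabled: list[ContextRule] = list(disabled)


@dataclass(frozen=True)
class AssertionStatus:
    """Assertion flags for one mention; default = affirmed patient mention."""

    negated: bool = False
    historical: bool = False
    experiencer: str = "patient"  # "patient" | "other"
    firing_rules: tuple[str, ...] = ()


@dataclass(frozen=True)
class AssertedMention:
    mention: Mention
    status: AssertionStatus


def is_positive_hit(am: AssertedMention, historical_counts_positive: bool = True) -> bool:
    """A hit counts toward note positivity iff affirmed and about the patient.

    Historical mentions count by default (housing history stays clinically
    relevant); pass ``historical_counts_positive=False`` to veto them.
    """
    if am.status.negated or am.status.experiencer != "patient":
        return False
    if am.status.historical and not historical_counts_positive:
        return False
    return True


_RULE_COLUMNS = [
    "rule_id", "trigger", "dimension", "value", "direction", "max_scope_tokens", "enabled",
]


def _parse_rule_row(row_no: int, fields: list[str]) -> ContextRule:
    if len(fields) != len(_RULE_COLUMNS):
        raise RuleFileError(
            f"row {row_no}: expected {len(_RULE_COLUMNS)} columns, got {len(fields)}"
        )
    rule_id, trigger, dimension, value, direction, max_tokens_raw, enabled_raw = (
        f.strip() for f in fields
    )
    if not rule_id:
        raise RuleFileError(f"row {row_no}: empty rule_id")
    if dimension not in DIMENSIONS:
        raise RuleFileError(f"row {row_no} ({rule_id}): unknown dimension {dimension!r}")
    if value not in _DIMENSION_VALUES[dimension]:
        raise RuleFileError(
            f"row {row_no} ({rule_id}): value {value!r} inconsistent with "
            f"dimension {dimension!r}"
        )
    if direction not in _DIRECTIONS:
        raise RuleFileError(f"row {row_no} ({rule_id}): unknown direction {direction!r}")
    max_tokens: Optional[int] = None
    if max_tokens_raw:
        try:
            max_tokens = int(max_tokens_raw)
        except ValueError:
            raise RuleFileError(
                f"row {row_no} ({rule_id}): max_scope_tokens must be an integer"
            ) from None
        if max_tokens <= 0:
            raise RuleFileError(f"row {row_no} ({rule_id}): max_scope_tokens must be positive")
    enabled = enabled_raw.lower() in {"1", "true", "yes", "y"}
    try:
        regex = compile_pattern(trigger)
    except LexiconError as exc:
        raise RuleFileError(f"row {row_no} ({rule_id}): {exc}") from None
    return ContextRule(
        rule_id=rule_id,
        trigger=trigger,
        dimension=dimension,
        value=value,
        direction=direction,
        max_scope_tokens=max_tokens,
        enabled=enabled,
        regex=regex,
    )


def load_context_rules(path: str | Path) -> RuleList:
    """Load a TSV context-rule file; returns enabled rules, disabled in ``.disabled``."""
    path = Path(path)
    raw = path.read_text(encoding="utf-8")
    lines = [
        (i + 1, line)
        for i, line in enumerate(raw.splitlines())
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not lines:
        raise RuleFileError(f"{path}: empty rule file")
    _header_no, header = lines[0]
    cols = [c.strip() for c in header.split("\t")]
    if cols != _RULE_COLUMNS:
        raise RuleFileError(f"{path}: header must be {_RULE_COLUMNS}, got {cols}")
    rules: list[ContextRule] = []
    seen_ids: set[str] = set()
    for row_no, line in lines[1:]:
        fields = next(csv.reader(io.StringIO(line), delimiter="\t"))
        rule = _parse_rule_row(row_no, fields)
        if rule.rule_id in seen_ids:
            raise RuleFileError(f"row {row_no}: duplicate rule_id {rule.rule_id!r}")
        seen_ids.add(rule.rule_id)
        rules.append(rule)
    return RuleList(
        enabled=[r for r in rules if r.enabled],
        disabled=[r for r in rules if not r.enabled],
    )


def default_rules_path() -> Path:
    return Path(str(resources.files("housenlp").joinpath("data/context_rules.tsv")))


def default_rules() -> RuleList:
    """Load the shipped default assertion rules."""
    return load_context_rules(default_rules_path())


def _token_spans(text: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in re.finditer(r"\S+", text)]


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def classify_context(
    mention: Mention, sentence: Sentence, rules: Sequence[ContextRule]
) -> AssertionStatus:
    """Assertion status of one mention within its sentence.

    For each dimension independently, an enabled trigger whose directional
    scope (clipped at termination terms, the token budget, and the sentence
    boundary) contains the mention sets that dimension's value. Triggers
    overlapping the mention itself, and triggers blocked by an overlapping
    pseudo-trigger of the same dimension, do not fire.
    """
    if not (sentence.start <= mention.start and mention.end <= sentence.end):
        raise ValueError(
            f"mention [{mention.start},{mention.end}) lies outside sentence "
            f"[{sentence.start},{sentence.end}) of note {sentence.note_id!r}"
        )
    text = sentence.text
    m_start = mention.start - sentence.start
    m_end = mention.end - sentence.start

    active = [r for r in rules if r.enabled]
    term_spans: list[tuple[int, int]] = []
    pseudo_spans: dict[str, list[tuple[int, int]]] = {}
    real: list[tuple[ContextRule, int, int]] = []
    for rule in active:
        for m in rule.regex.finditer(text):
            span = (m.start(), m.end())
            if rule.is_termination:
                term_spans.append(span)
            elif rule.is_pseudo:
                pseudo_spans.setdefault(rule.dimension, []).append(span)
            else:
                real.append((rule, *span))

    tokens = _token_spans(text)
    values: dict[str, str] = {}
    firing: set[str] = set()
    for rule, t_start, t_end in real:
        if _overlaps(t_start, t_end, m_start, m_end):
            continue  # trigger inside/overlapping the concept itself
        if any(
            _overlaps(t_start, t_end, p_start, p_end)
            for p_start, p_end in pseudo_spans.get(rule.dimension, ())
        ):
            continue  # blocked by a pseudo-trigger
        fired = False
        if rule.direction in ("forward", "bidirectional") and m_start >= t_end:
            scope_end = len(text)
            for s, _e in term_spans:
                if s >= t_end:
                    scope_end = min(scope_end, s)
            if rule.max_scope_tokens is not None:
                after = [t for t in tokens if t[0] >= t_end]
                if len(after) > rule.max_scope_tokens:
                    scope_end = min(scope_end, after[rule.max_scope_tokens - 1][1])
            fired = m_start < scope_end
        if not fired and rule.direction in ("backward", "bidirectional") and m_end <= t_start:
            scope_start = 0
            for _s, e in term_spans:
                if e <= t_start:
                    scope_start = max(scope_start, e)
            if rule.max_scope_tokens is not None:
                before = [t for t in tokens if t[1] <= t_start]
                if len(before) > rule.max_scope_tokens:
                    scope_start = max(scope_start, before[-rule.max_scope_tokens][0])
            fired = m_start >= scope_start
        if fired:
            values[rule.dimension] = rule.value
            firing.add(rule.rule_id)

    return AssertionStatus(
        negated=values.get("negation") == "negated",
        historical=values.get("temporality") == "historical",
        experiencer="other" if values.get("experiencer") == "other_experiencer" else "patient",
        firing_rules=tuple(sorted(firing)),
    )


def assert_corpus(
    mentions_by_note: dict[str, list[Mention]],
    sentences_by_note: dict[str, list[Sentence]],
    rules: Sequence[ContextRule],
) -> list[AssertedMention]:
    """Classify every mention against its own sentence; order preserved."""
    out: list[AssertedMention] = []
    for note_id, mentions in mentions_by_note.items():
        sentences = sentences_by_note.get(note_id)
        if sentences is None:
            raise ValueError(f"no sentences supplied for note {note_id!r}")
        by_index = {s.index: s for s in sentences}
        for mention in mentions:
            sentence = by_index.get(mention.sentence_index)
            if sentence is None:
                raise ValueError(
                    f"note {note_id!r}: no sentence with index {mention.sentence_index}"
                )
            out.append(AssertedMention(mention, classify_context(mention, sentence, rules)))
    return out
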
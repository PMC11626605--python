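"""Housing lexicon: loading, validation, and phrase-to-pattern compression.

The lexicon maps six housing-related concepts (homeless, unstable housing,
recovery housing, emergency housing, temporary housing, exposure) to
patterns written in a small, declared dialect: literals, alternation
``(a|b)``, optional groups ``(x)?``, and character classes. Two conventions
make patterns robust to clinical text:

* a literal space stands for one-or-more whitespace characters;
* `` (word)? `` — an optional group flanked by spaces — means an optional
  word together with one of its neighbouring whitespace runs, so
  ``living on the (the)? street(s)?`` accepts both "living on the street"
  and "living on the the streets".

Compiled patterns are anchored at word boundaries on both ends and matched
case-insensitively unless an entry opts out. Every entry carries the literal
phrases it was compressed from, and each phrase is re-matched against its
own compiled pattern at load time (the round-trip check), so a lexicon that
loads is a lexicon that works.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ConceptCategory",
    "LexiconEntry",
    "CompiledLexicon",
    "LexiconError",
    "compile_pattern",
    "compress_phrases",
    "load_lexicon",
    "default_lexicon_path",
    "default_lexicon",
    "validate_flexibility",
]

SUPPORTED_DIALECTS = ("pcre-subset",)


class LexiconError(ValueError):
    """Raised for malformed lexicon files or non-compiling patterns."""


class ConceptCategory(str, Enum):
    """The six housing concepts every mention must belong to."""

    HOMELESS = "homeless"
    UNSTABLE_HOUSING = "unstable_housing"
    RECOVERY_HOUSING = "recovery_housing"
    EMERGENCY_HOUSING = "emergency_housing"
    TEMPORARY_HOUSING = "temporary_housing"
    EXPOSURE = "exposure"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# " (word)? " -> optional word absorbing one neighbouring whitespace run
_OPTIONAL_WORD = re.compile(r" \(([^()?]+)\)\? ")


def compile_pattern(
    pattern: str,
    case_sensitive: bool = False,
    word_boundaries: bool = True,
) -> re.Pattern[str]:
    """Compile a dialect pattern string to a regular expression.

    Spaces become ``\\s+``; optional words flanked by spaces absorb one
    whitespace run; the whole pattern is wrapped in ``\\b(?:...)\\b``
    unless *word_boundaries* is False.
    """
    src = pattern.strip()
    if not src:
        raise LexiconError("empty pattern")
    while True:
        rewritten = _OPTIONAL_WORD.sub(r" (?:\1 )?", src)
        if rewritten == src:
            break
        src = rewritten
    src = re.sub(r" +", r"\\s+", src)
    if word_boundaries:
        src = r"\b(?:%s)\b" % src
    flags = 0 if case_sensitive else re.IGNORECASE
    try:
        return re.compile(src, flags)
    except re.error as exc:
        raise LexiconError(f"pattern {pattern!r} does not compile: {exc}") from exc


@dataclass(frozen=True)
class LexiconEntry:
    """One lexicon row: a concept, its pattern, and the phrases it covers."""

    concept: ConceptCategory
    pattern: str
    source_phrases: tuple[str, ...]
    case_sensitive: bool = False
    notes: str = ""
    entry_id: int = 0
    regex: re.Pattern[str] = field(repr=False, compare=False, default=None)  # type: ignore[assignment]

    def matches(self, text: str) -> bool:
        return self.regex.search(text) is not None


@dataclass(frozen=True)
class CompiledLexicon:
    """An ordered, validated collection of compiled lexicon entries."""

    entries: tuple[LexiconEntry, ...]
    version: str = "0"
    source_path: str = "<memory>"

    def __iter__(self) -> Iterable[LexiconEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def concepts(self) -> set[ConceptCategory]:
        return {e.concept for e in self.entries}


def _trie_insert(root: dict, phrase: str) -> None:
    node = root
    for ch in phrase:
        node = node.setdefault(ch, {})
    node[None] = {}  # end-of-phrase marker


def _trie_pattern(node: dict) -> str:
    """Emit a regex accepting exactly the phrases below *node* (prefix-factored)."""
    alternatives = []
    for ch in sorted(k for k in node if k is not None):
        sub = node[ch]
        chain = re.escape(ch)
        # collapse single-child chains into a literal run
        while len(sub) == 1 and None not in sub:
            (nxt, sub), = sub.items()
            chain += re.escape(nxt)
        alternatives.append(chain + _trie_pattern(sub))
    ends_here = None in node
    if not alternatives:
        return ""
    if len(alternatives) == 1 and not ends_here:
        return alternatives[0]
    body = "(?:" + "|".join(alternatives) + ")"
    return body + ("?" if ends_here else "")


def compress_phrases(phrases: Sequence[str]) -> str:
    """Compress literal phrases into one pattern accepting exactly their union.

    Shared prefixes are factored through a character trie, so
    ``["lack of housing", "lack of shelter"]`` compresses to a pattern
    equivalent to ``lack of (shelter|housing)``. Equivalence is behavioural:
    the returned pattern full-matches a string iff the string is one of the
    input phrases.
    """
    if not phrases:
        raise LexiconError("compress_phrases requires at least one phrase")
    for p in phrases:
        if not p:
            raise LexiconError("phrases must be non-empty strings")
    root: dict = {}
    for p in sorted(set(phrases)):
        _trie_insert(root, p)
    return _trie_pattern(root)


_LEXICON_COLUMNS = ["concept", "pattern", "source_phrases", "case_sensitive", "notes"]
_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n", ""}


def _parse_bool(raw: str, row_no: int, what: str) -> bool:
    val = raw.strip().lower()
    if val in _TRUTHY:
        return True
    if val in _FALSY:
        return False
    raise LexiconError(f"row {row_no}: {what} must be boolean, got {raw!r}")


def load_lexicon(
    path: str | Path,
    dialect: str = "pcre-subset",
    require_full_coverage: bool = False,
) -> CompiledLexicon:
    """Load and validate a TSV lexicon file.

    The file has columns {concept, pattern, source_phrases, case_sensitive,
    notes}; source_phrases is ``|``-separated; lines starting with ``#`` are
    ignored. Validation is strict and fatal: unknown concept names,
    non-compiling patterns, and source phrases not matched by their own
    pattern all abort the load, naming the offending row.
    ``require_full_coverage`` additionally demands at least one entry per
    concept (the shipped default lexicon is held to this).
    """
    if dialect not in SUPPORTED_DIALECTS:
        raise LexiconError(f"unsupported pattern dialect {dialect!r}")
    path = Path(path)
    raw = path.read_text(encoding="utf-8")
    lex = _parse_lexicon(raw, source_path=str(path))
    if require_full_coverage:
        missing = set(ConceptCategory) - lex.concepts()
        if missing:
            raise LexiconError(
                f"{path}: lexicon misses concepts: {sorted(str(c) for c in missing)}"
            )
    return lex


def _parse_lexicon(raw: str, source_path: str) -> CompiledLexicon:
    lines = [
        (i + 1, line)
        for i, line in enumerate(raw.splitlines())
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not lines:
        raise LexiconError(f"{source_path}: empty lexicon file")
    header_no, header = lines[0]
    cols = [c.strip() for c in header.split("\t")]
    if cols != _LEXICON_COLUMNS:
        raise LexiconError(
            f"{source_path}: header must be {_LEXICON_COLUMNS}, got {cols}"
        )
    entries: list[LexiconEntry] = []
    for row_no, line in lines[1:]:
        fields = next(csv.reader(io.StringIO(line), delimiter="\t"))
        if len(fields) != len(_LEXICON_COLUMNS):
            raise LexiconError(
                f"row {row_no}: expected {len(_LEXICON_COLUMNS)} columns, got {len(fields)}"
            )
        concept_raw, pattern, phrases_raw, cs_raw, notes = fields
        try:
            concept = ConceptCategory(concept_raw.strip())
        except ValueError:
            raise LexiconError(
                f"row {row_no}: unknown concept {concept_raw!r}"
            ) from None
        phrases = tuple(p.strip() for p in phrases_raw.split("|") if p.strip())
        if not phrases:
            raise LexiconError(f"row {row_no}: source_phrases must be non-empty")
        case_sensitive = _parse_bool(cs_raw, row_no, "case_sensitive")
        try:
            regex = compile_pattern(pattern, case_sensitive=case_sensitive)
        except LexiconError as exc:
            raise LexiconError(f"row {row_no}: {exc}") from None
        for phrase in phrases:
            if regex.search(phrase) is None:
                raise LexiconError(
                    f"row {row_no}: source phrase {phrase!r} is not matched "
                    f"by its own pattern {pattern!r}"
                )
        entries.append(
            LexiconEntry(
                concept=concept,
                pattern=pattern.strip(),
                source_phrases=phrases,
                case_sensitive=case_sensitive,
                notes=notes.strip(),
                entry_id=len(entries),
                regex=regex,
            )
        )
    if not entries:
        raise LexiconError(f"{source_path}: lexicon has no entries")
    return CompiledLexicon(entries=tuple(entries), version="1", source_path=source_path)


def default_lexicon_path() -> Path:
    """Filesystem path of the packaged default lexicon TSV."""
    return Path(str(resources.files("housenlp").joinpath("data/lexicon.tsv")))


def default_lexicon() -> CompiledLexicon:
    """Load the shipped default housing lexicon; all six concepts must be covered."""
    return load_lexicon(default_lexicon_path(), require_full_coverage=True)


def validate_flexibility(
    entry: LexiconEntry, probes: Sequence[str]
) -> list[tuple[str, bool]]:
    """Report, per probe string, whether the entry's compiled pattern matches it."""
    return [(probe, entry.matches(probe)) for probe in probes]
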
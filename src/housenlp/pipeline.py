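"""End-to-end orchestration: read notes, extract, assert, classify, write.

Outputs are plain, diff-able standoff files: a JSONL with one object per
asserted mention, a note-label CSV, a concept-distribution CSV, and a run
manifest. Given identical config and inputs the data files are
byte-identical (timestamps live only in the manifest's log section, never
in data). Offsets everywhere are 0-based half-open code-point spans, and a
span-fidelity validator re-checks every record against the note text
before it is written.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .classify import AnnotatedNote, annotate_note, concept_distribution
from .context import RuleList, default_rules, load_context_rules
from .lexicon import CompiledLexicon, default_lexicon, load_lexicon
from .segmenter import ClinicalNote

__all__ = ["RunConfig", "ConfigError", "DataError", "read_notes", "write_annotations", "run_pipeline"]

log = logging.getLogger("housenlp")


class ConfigError(ValueError):
    """Bad run configuration (missing paths, unknown options)."""


class DataError(ValueError):
    """Bad input data (duplicate ids, undecodable files)."""


@dataclass
class RunConfig:
    input: str | Path
    output_dir: str | Path
    lexicon_path: Optional[str | Path] = None  # None = shipped default
    context_rules_path: Optional[str | Path] = None
    historical_counts_positive: bool = True
    distribution_basis: str = "positive_hits"
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.distribution_basis not in ("positive_hits", "all_hits"):
            raise ConfigError(f"unknown distribution_basis {self.distribution_basis!r}")
        if not Path(self.input).exists():
            raise ConfigError(f"input path does not exist: {self.input}")
        for p in (self.lexicon_path, self.context_rules_path):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"path does not exist: {p}")

    def to_dict(self) -> dict:
        return {
            "input": str(self.input),
            "output_dir": str(self.output_dir),
            "lexicon_path": str(self.lexicon_path) if self.lexicon_path else None,
            "context_rules_path": str(self.context_rules_path) if self.context_rules_path else None,
            "historical_counts_positive": self.historical_counts_positive,
            "distribution_basis": self.distribution_basis,
        }


def read_notes(input_path: str | Path) -> list[ClinicalNote]:
    """Read notes from a directory of .txt files or a CSV with note_id,text.

    Directory reads are lexicographic by filename; the filename stem is the
    note id. Decoding is strict UTF-8 — an undecodable file is an error,
    not a silent replacement.
    """
    input_path = Path(input_path)
    notes: list[ClinicalNote] = []
    seen: set[str] = set()

    def add(note_id: str, text: str, source: str) -> None:
        if note_id in seen:
            raise DataError(f"duplicate note_id {note_id!r} (from {source})")
        seen.add(note_id)
        notes.append(ClinicalNote(note_id=note_id, text=text, meta={"source": source}))

    if input_path.is_dir():
        for p in sorted(input_path.rglob("*.txt")):
            try:
                text = p.read_text(encoding="utf-8")
            except UnicodeDecodeError as exc:
                raise DataError(f"{p}: not valid UTF-8: {exc}") from None
            add(p.stem, text, str(p))
    elif input_path.suffix.lower() == ".csv":
        with open(input_path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"note_id", "text"} <= set(reader.fieldnames):
                raise DataError(f"{input_path}: CSV needs columns note_id,text")
            for row in reader:
                add(row["note_id"], row["text"], str(input_path))
    else:
        raise ConfigError(f"input must be a directory or a .csv file: {input_path}")
    return notes


def _mention_record(annotated: AnnotatedNote, am) -> dict:
    m, s = am.mention, am.status
    if annotated.note.text[m.start:m.end] != m.matched_text:
        raise DataError(
            f"span-fidelity violation in note {m.note_id!r} at [{m.start},{m.end})"
        )
    return {
        "note_id": m.note_id,
        "sentence_index": m.sentence_index,
        "concept": str(m.concept),
        "matched_text": m.matched_text,
        "start": m.start,
        "end": m.end,
        "negated": s.negated,
        "historical": s.historical,
        "experiencer": s.experiencer,
        "firing_rules": list(s.firing_rules),
    }


def write_annotations(
    annotated: Sequence[AnnotatedNote], outdir: str | Path, basis: str = "positive_hits"
) -> dict[str, str]:
    """Write mentions.jsonl, note_labels.csv and concept_distribution.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    mentions_path = outdir / "mentions.jsonl"
    with open(mentions_path, "w", encoding="utf-8") as fh:
        for note in annotated:
            for am in note.asserted_mentions:
                fh.write(json.dumps(_mention_record(note, am), sort_keys=True) + "\n")
    paths["mentions"] = str(mentions_path)

    labels_path = outdir / "note_labels.csv"
    with open(labels_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["note_id", "label", "n_mentions", "n_positive_hits"])
        for note in annotated:
            writer.writerow(
                [note.note.note_id, note.label, len(note.asserted_mentions), note.n_positive_hits]
            )
    paths["labels"] = str(labels_path)

    dist = concept_distribution(list(annotated), basis=basis)
    dist_path = outdir / "concept_distribution.csv"
    with open(dist_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["concept", "count", "basis"])
        for concept, count in dist.counts.items():
            writer.writerow([str(concept), count, dist.basis])
    paths["distribution"] = str(dist_path)
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full extraction run and return the manifest.

    Failure removes any partial data files already written to output_dir.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    lexicon: CompiledLexicon = (
        load_lexicon(config.lexicon_path) if config.lexicon_path else default_lexicon()
    )
    rules: RuleList = (
        load_context_rules(config.context_rules_path)
        if config.context_rules_path
        else default_rules()
    )
    notes = read_notes(config.input)
    if not notes:
        log.warning("no notes found under %s", config.input)

    annotated = [
        annotate_note(n, lexicon, rules, config.historical_counts_positive) for n in notes
    ]

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    try:
        written = write_annotations(annotated, outdir, basis=config.distribution_basis)
        input_hash = hashlib.sha256(
            "".join(f"{n.note_id}\x00{n.text}\x01" for n in notes).encode("utf-8")
        ).hexdigest()
        manifest = {
            "tool": {"name": "housenlp", "version": __version__},
            "config": config.to_dict(),
            "lexicon": {"source": lexicon.source_path, "entries": len(lexicon)},
            "rules": {"enabled": len(rules), "disabled": len(getattr(rules, "disabled", []))},
            "input": {"n_notes": len(notes), "sha256": input_hash},
            "counts": {
                "mentions": sum(len(a.asserted_mentions) for a in annotated),
                "positive_notes": sum(1 for a in annotated if a.label == "positive"),
                "negative_notes": sum(1 for a in annotated if a.label == "negative"),
            },
            "outputs": written,
        }
        manifest_path = outdir / "run_manifest.json"
        manifest_path.write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        written["manifest"] = str(manifest_path)
        return manifest
    except Exception:
        for p in written.values():
            Path(p).unlink(missing_ok=True)
        raise
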
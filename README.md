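# housenlp

Rule-based extraction of housing-instability concepts from clinical notes.

Housing is an environmental social determinant of health: unstable housing
and homelessness are linked to higher emergency-department reliance,
readmissions, and mortality, yet they are chronically under-coded in
structured EHR data — much of the signal lives only in free-text notes.
`housenlp` is a small, fully deterministic engine for surfacing that
signal, aimed at clinical-informatics teams who need a transparent,
auditable alternative to black-box models for phenotyping and cohort
discovery.

## Method

1. **Lexicon.** Six housing concepts — *homeless, unstable housing,
   recovery housing, emergency housing, temporary housing, exposure* —
   each mapped to flexible patterns compressed from literal phrases
   (e.g. `lack of (shelter|housing)`, `living on the (the)? street(s)?`,
   including the common misspelling `homelesss`). Every pattern is
   validated at load time against the phrases it claims to cover.
2. **Sentence segmentation** with exact 0-based half-open character
   offsets. Assertion scope is sentence-bounded, so segmentation fixes
   every contextual window downstream.
3. **Matching.** All lexicon hits per sentence, resolved
   leftmost-longest (so "homeless shelter" is one emergency-housing
   mention, not two).
4. **Assertion (ConText-style).** Trigger terms project directional
   scopes that classify each mention as negated ("denies being
   homeless"), historical ("history of homelessness"), or about another
   experiencer ("her brother is homeless"); termination terms ("but",
   "however") clip scopes, pseudo-triggers ("no increase") block false
   firings, and test-result negations ("did not demonstrate") ship
   disabled because housing is not a finding one tests positive for.
5. **Note classification.** A note is *positive* for housing issues iff
   any mention is affirmed and about the patient; notes with no housing
   language, or only negated / other-experiencer mentions, are
   *negative*. Precision = TP/(TP+FP) and recall = TP/(TP+FN) are
   computed at note level; undefined ratios are reported as N/A, never 0.

A template-based generator produces labeled synthetic ED discharge notes
(affirmed / negated / absent classes, plus adversarial family-member,
third-party, and resource-list classes) so the whole pipeline is testable
without any real EHR data.

## Worked example

```bash
housenlp synth --n 20 --seed 42 --out demo/corpus
# wrote 20 notes (8 positive) to demo/corpus (22 files)

housenlp extract --in demo/corpus/notes --out demo/run
# 20 notes, 14 mentions, 8 positive / 12 negative

housenlp evaluate --pred demo/run/note_labels.csv --gold demo/corpus/gold.csv
# note-level evaluation (n=20)
#   TP=8  FP=0  TN=12  FN=0
#   precision=1.0000  recall=1.0000  F1=1.0000
```

The synthetic corpus contains 8 notes with an affirmed housing problem,
6 with an explicitly negated one, and 6 with no housing language; the
pipeline recovers exactly the 8 positives (TP=8, TN=12, no errors), hence
precision and recall of 1.0. `demo/run/mentions.jsonl` holds one standoff
record per mention, offsets verified against the note text:

```json
{"concept": "homeless", "start": 347, "end": 368,
 "matched_text": "living on the streets", "negated": false,
 "historical": false, "experiencer": "patient",
 "note_id": "note_0001", "sentence_index": 7, "firing_rules": []}
```

The same run also writes `note_labels.csv` and a per-concept
distribution (`concept_distribution.csv`), counted over positive hits by
default (`--all-hits` to count every mention).

The library mirrors the CLI: `generate_corpus`, `annotate_note`,
`evaluate_notes`, etc. — see the module docstrings and
`docs/methods.md`.

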
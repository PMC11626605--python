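# Methods

## Problem and approach

Housing instability is documented in clinical text far more often than in
structured codes, usually as short declarative statements ("patient is
homeless", "staying in a shelter"), frequently negated ("denies
homelessness") or attributed to someone else ("her brother is homeless").
`housenlp` treats extraction as a transparent, fully rule-based pipeline:
dictionary matching over sentences, ConText-style assertion, and an
any-positive-hit note label. Every stage is deterministic — identical
inputs and configuration produce byte-identical outputs — which is what
makes the system auditable in a clinical-informatics setting.

## Lexicon and pattern dialect

Patterns are written in a deliberately small dialect: literals,
alternation `(a|b)`, optional groups `(x)?`, character classes. Three
compilation conventions are applied uniformly:

* a literal space compiles to `\s+` (clinical text has irregular spacing);
* an optional group flanked by spaces, ` (word)? `, absorbs one of its
  neighbouring whitespace runs, so `living on the (the)? street(s)?`
  accepts "living on the street", "living on the streets", and the
  doubled-article form;
* the whole pattern is wrapped in `\b(?:...)\b` and matched
  case-insensitively unless the entry opts out.

Word-boundary anchoring interacts with morphology: "homelessness" must
match the homeless concept, so the stem entry is `homeless(ness|s)?` —
the suffix alternation covers the noun form and the common misspelling
`homelesss` — rather than relying on boundary-free substring matching,
which would accept arbitrary embeddings.

`compress_phrases` turns a list of literal phrases into one pattern
accepting exactly their union, via a character-trie with shared-prefix
factoring. Its correctness criterion is behavioural (full-match accepts
members, rejects non-members), which the tests check against a literal
set-membership oracle with random near-miss perturbations.

Only three patterns of the shipped lexicon have a quoted provenance
(`lack of (shelter|housing)`, the flexible street pattern, and the
misspelling); the remaining entries are curated concept-typical phrases,
flagged as such in the `notes` column so the two tiers stay separable.

## Segmentation

Sentences carry exact 0-based half-open code-point offsets; spans include
terminal punctuation and exclude surrounding whitespace. Every line break
is a hard boundary — clinical notes are strongly line-oriented, and this
isolates section headers ("PATIENT EDUCATION:") and resource-list items
on their own lines, which the error-bucketing stage relies on. Within a
line, `.`/`!`/`?` followed by whitespace ends a sentence, except after a
protected abbreviation set (Dr., pt., hx., b.i.d., ...) and inside
decimal numbers. The cost of the line-break rule is that a prose sentence
hard-wrapped across lines is split; for assertion scope this errs on the
conservative side (scopes get shorter, never longer).

## Matching

All lexicon regexes run per sentence; candidates are resolved
leftmost-first, longest-at-a-position, ties by lexicon file order, and
any candidate overlapping an accepted match is suppressed. One span
yields exactly one mention, so concept distributions never double-count.
For pure-literal lexicons the matcher is property-tested against a naive
case-folded substring scan with word-boundary checks.

## Assertion (ConText)

Each of the three dimensions — negation, temporality, experiencer — is
decided independently. An enabled trigger projects a scope forward (to
sentence end) or backward (to sentence start), clipped at termination
terms and, when a rule sets `max_scope_tokens`, at a whitespace-token
budget; the default is unbounded within the sentence, because sentence
windowing is the primary scope control. A trigger overlapping the mention
itself never fires (so "no fixed abode" is not self-negated), and a
pseudo-trigger (`value=none`) blocks any real trigger of its dimension
that it overlaps. The default status is affirmed / current / patient.

The shipped rule file is a reconstruction of the standard trigger
families: forward negations (no, not, denies, without, ...), two backward
negations (ruled out, unlikely), pseudo-triggers (not only, no increase,
...), temporality (history of, h/o, hx of), an experiencer family-member
list, and global termination terms (but, however, except, ...). The
"did not demonstrate" family is present but disabled — housing issues are
not findings a patient tests positive or negative for — and disabled
rules are returned in an audit list rather than dropped.

Two behaviours are deliberate reproductions of known limitations of this
rule family, pinned by golden tests rather than "fixed":

* scope confusion — in "Patient is not safe candidate for home IV abx
  therapy given active IVDA and homelessness", the forward scope of
  "not" reaches "homelessness", producing a hit-level false negative;
* third-party mentions — "a homeless person sleeping in her bathroom"
  carries no rule-usable marker that the person is not the patient and
  remains a designed false positive.

Historical mentions count toward note positivity by default (housing
history is clinically relevant and positivity is defined via negation,
not temporality); `historical_counts_positive=False` flips this.

## Note classification and distributions

A note is positive iff at least one mention is a positive hit
(not negated, experiencer = patient). Concept distributions default to
counting positive hits — the basis that matches a cohort reading such as
"patients staying in shelters" — with `all_hits` as the override. A
patient-level rollup (any positive note ⇒ positive patient) is provided
as a convenience but is not part of the note-level metric.

## Evaluation

Note-level scoring is a strict confusion matrix over exactly-paired
prediction/gold ids. Hit-level scoring aligns predicted to gold mentions
by ≥1-character span overlap plus concept agreement (the least brittle
convention); when several predictions align to one gold mention the
leftmost is scored and the rest are ignored rather than penalized.
Undefined ratios are `None`/"N/A": an `EvalResult` built in
`precision_only` mode (gold = system hits reviewed for correctness, so
false negatives are unobservable) has no recall at all. Error cases are
bucketed into resource-list FPs (header match), family-member FPs
(experiencer word), third-party FPs (generic-person phrase), and
negation-scope FNs (negation word present).

## Synthetic corpus generator

The generator emulates a formulaic, shareable ED-discharge test corpus:
fixed skeleton (chief complaint, HPI, exam, plan, patient education,
disposition), one injected housing scenario per note, gold note label and
a per-injection ledger (phrase, concept, class, sentence index). Defaults
are the study conditions used throughout: 200 notes, 40% affirmed / 30%
negated / 30% absent, seed 42. Class and concept counts are apportioned
by largest remainder, so they are exact; the seeded RNG chooses only
templates and phrases, giving cross-platform byte determinism.

What the generator does *not* emulate: real notes' typos and ungrammatical
shorthand, template diversity beyond the shipped pools, temporal structure
across notes, or the statistics of any real cohort. Consequently, perfect
precision/recall on the formulaic corpus shows the pipeline wiring is
errorless under clean conditions — the same reading one should give any
formulaic synthetic benchmark — and says nothing quantitative about
performance on real EHR text, where resource lists, third-party mentions
and scope confusions (all reproducible here via the adversarial classes)
degrade it. The phrasing "no visible signs of homelessness", unlikely in
a real note, is excluded from the default templates and retained only as
an optional adversarial constant.

## Numerical and degenerate-input choices

* Offsets: 0-based, half-open, Unicode code points, everywhere.
* Empty note text → zero sentences, zero mentions, negative label.
* Empty evaluation → all ratios undefined (N/A), n = 0.
* Proportion validation tolerance: 1e-9 on the sum.
* Apportionment ties break by canonical class/concept order.
* Exit codes: 0 success (even with zero hits), 2 config error, 3 data
  error.

## Problem sizes

The test suite uses corpora of 10–200 notes and 1,000-sentence random
matcher checks; the reproduction script uses the 200-note default corpus.
All runs complete in seconds on a single CPU.

## Known limitations

Third-party mentions are unfixable within this rule family (no
contextual marker); hard-wrapped prose sentences are over-segmented; the
lexicon's breadth is bounded by curation, and language describing housing
changes over time; temporality across notes and explicit *stable*-housing
mentions are out of scope.
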
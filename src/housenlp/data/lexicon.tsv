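# Default housing lexicon (version 1).
# Columns: concept, pattern, source_phrases (|-separated), case_sensitive, notes.
# Pattern dialect: literals, alternation (a|b), optional groups (x)?,
# a literal space = one-or-more whitespace; compiled with word boundaries,
# case-insensitive. Rows marked paper-verbatim carry patterns quoted in the
# method description; the rest are curated concept-typical phrases.
concept	pattern	source_phrases	case_sensitive	notes
homeless	homeless(ness|s)?	homeless|homelessness|homelesss	false	paper-verbatim: stem form covering homelessness and the common misspelling homelesss
homeless	lack of (shelter|housing)	lack of housing|lack of shelter	false	paper-verbatim: compressed from two phrases
homeless	living on the (the)? street(s)?	living on the street|living on the streets	false	paper-verbatim: flexible pattern, optional article and plural
homeless	unhoused	unhoused	false	curated
homeless	sleeping on the street(s)?	sleeping on the street|sleeping on the streets	false	curated
homeless	no fixed (abode|address)	no fixed abode|no fixed address	false	curated
unstable_housing	housing (instability|insecurity)	housing instability|housing insecurity	false	curated
unstable_housing	(unstable|precarious|inadequate) housing	unstable housing|precarious housing|inadequate housing	false	curated
unstable_housing	couch (surfing|surfer)	couch surfing|couch surfer	false	curated
unstable_housing	(facing|threat of) eviction	facing eviction|threat of eviction	false	curated
recovery_housing	recovery (housing|house|residence)	recovery housing|recovery house|recovery residence	false	curated
recovery_housing	sober living( home| house| environment| facility)?	sober living|sober living home|sober living house	false	curated
recovery_housing	halfway house	halfway house	false	curated
recovery_housing	oxford house	oxford house	false	curated
emergency_housing	emergency (housing|shelter|accommodation)	emergency housing|emergency shelter|emergency accommodation	false	curated
emergency_housing	homeless shelter	homeless shelter	false	curated; wins over the homeless stem by leftmost-longest
emergency_housing	warming (center|centre|shelter)	warming center|warming shelter	false	curated
temporary_housing	temporary (housing|shelter|accommodation|residence)	temporary housing|temporary shelter	false	curated
temporary_housing	(staying|stays|stayed) (in|at) (a|the) shelter	staying in a shelter|staying at the shelter|stays in a shelter	false	curated
temporary_housing	living in a shelter	living in a shelter	false	curated
temporary_housing	transitional (housing|living)	transitional housing|transitional living	false	curated
exposure	(cold|heat) exposure	cold exposure|heat exposure	false	curated
exposure	exposure to the (elements|cold|heat)	exposure to the elements|exposure to the cold	false	curated
exposure	exposed to the (elements|cold|heat)	exposed to the elements|exposed to the cold	false	curated
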
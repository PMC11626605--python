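# Default ConText-style assertion rules (version 1).
# Columns: rule_id, trigger, dimension, value, direction, max_scope_tokens, enabled.
# Trigger patterns use the lexicon dialect (space = whitespace run; word
# boundaries; case-insensitive). Empty max_scope_tokens = unbounded within
# the sentence. value=none rows are pseudo-triggers that block real triggers
# they overlap. dimension=termination rows end any trigger's scope.
# Test-result negations ("did not demonstrate" family) ship disabled:
# housing issues are not findings a patient tests positive or negative for.
rule_id	trigger	dimension	value	direction	max_scope_tokens	enabled
neg_no	no	negation	negated	forward		true
neg_not	not	negation	negated	forward		true
neg_denies	denies	negation	negated	forward		true
neg_denied	denied	negation	negated	forward		true
neg_without	without	negation	negated	forward		true
neg_never	never	negation	negated	forward		true
neg_no_evidence_of	no evidence of	negation	negated	forward		true
neg_negative_for	negative for	negation	negated	forward		true
neg_free_of	free of	negation	negated	forward		true
neg_ruled_out	ruled out	negation	negated	backward		true
neg_unlikely	unlikely	negation	negated	backward		true
pseudo_not_only	not only	negation	none	forward		true
pseudo_no_increase	no increase	negation	none	forward		true
pseudo_no_change	no change	negation	none	forward		true
pseudo_not_certain_if	not certain if	negation	none	forward		true
pseudo_not_necessarily	not necessarily	negation	none	forward		true
did_not_demonstrate	did not demonstrate	negation	negated	forward		false
does_not_demonstrate	does not demonstrate	negation	negated	forward		false
did_not_exhibit	did not exhibit	negation	negated	forward		false
did_not_reveal	did not reveal	negation	negated	forward		false
did_not_show	did not show	negation	negated	forward		false
hist_history_of	history of	temporality	historical	forward		true
hist_h_o	h/o	temporality	historical	forward		true
hist_hx_of	hx of	temporality	historical	forward		true
hist_past_history	past history of	temporality	historical	forward		true
exp_family_member	family member(s)?	experiencer	other_experiencer	forward		true
exp_brother	brother	experiencer	other_experiencer	forward		true
exp_sister	sister	experiencer	other_experiencer	forward		true
exp_mother	mother	experiencer	other_experiencer	forward		true
exp_father	father	experiencer	other_experiencer	forward		true
exp_aunt	aunt	experiencer	other_experiencer	forward		true
exp_uncle	uncle	experiencer	other_experiencer	forward		true
exp_grandmother	grandmother	experiencer	other_experiencer	forward		true
exp_grandfather	grandfather	experiencer	other_experiencer	forward		true
exp_wife	wife	experiencer	other_experiencer	forward		true
exp_husband	husband	experiencer	other_experiencer	forward		true
exp_son	son	experiencer	other_experiencer	forward		true
exp_daughter	daughter	experiencer	other_experiencer	forward		true
exp_cousin	cousin	experiencer	other_experiencer	forward		true
exp_roommate	roommate	experiencer	other_experiencer	forward		true
exp_neighbor	neighbor	experiencer	other_experiencer	forward		true
term_but	but	termination	terminate	bidirectional		true
term_however	however	termination	terminate	bidirectional		true
term_except	except	termination	terminate	bidirectional		true
term_although	although	termination	terminate	bidirectional		true
term_though	though	termination	terminate	bidirectional		true
term_aside_from	aside from	termination	terminate	bidirectional		true
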
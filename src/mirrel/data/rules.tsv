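# Default lexico-syntactic rule inventory.
# Columns: pattern_id	role	trigger_form	voice	expr
# role: agent | theme | self | other.  For entity-noun triggers, "self" is
# the role the noun itself denotes (the referential phrase) and "other" is
# the opposite role, filled by the of-/for-argument or a premodifier.
agent:NP-VP	agent	verb	active	(S < NP=arg < (VP <h VB*=trig))
theme:NP-VP	theme	verb	active	(VP <h VB*=trig < NP=arg)
theme:VP-to-NP	theme	verb	active	(VP <h VB*=trig < (PP < (TO|IN "to") < NP=arg))
theme:NP-VP-passive	theme	verb	passive	(S < NP=arg < (VP <h VB*=trig))
agent:VP-by-NP	agent	verb	passive	(VP <h VB*=trig << (PP < (IN "by") < NP=arg))
theme:NP-of-NP-1	theme	process_noun	any	(NP < (NP < NN*=trig) < (PP < (IN "of") < NP=arg))
agent:NP-by-NP	agent	process_noun	any	(NP < (NP < NN*=trig) < (PP < (IN "by") < NP=arg))
theme:NP-to-NP	theme	process_noun	any	(NP < (NP < NN*=trig) < (PP < (TO|IN "to") < NP=arg))
agent:NP-of-to	agent	process_noun	any	(NP < (NP < NN*=trig) < (PP < (IN "of") < NP=arg) < (PP < (TO|IN "to") < NP))
self:entity-noun	self	entity_noun	any	(NP=arg < NN*=trig)
other:NP-of-NP-2	other	entity_noun	any	(NP < (NP < NN*=trig) < (PP < (IN "of|for") < NP=arg))
other:premod	other	entity_noun	any	(NP < NN*|PRP$=arg < NN*=trig)
agent:null-arg-VP	agent	verb	active	(S|SBAR < NP|WHNP=arg << (PP < (IN "by|via|through|upon|after") < (S|VP <h VB*=trig)))
theme:JJ-NP	theme	adjective	any	(NP < JJ*=trig < NN*=arg)
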
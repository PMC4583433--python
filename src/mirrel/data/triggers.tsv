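# Seed trigger lexicon.  Columns (tab-separated):
# lemma	noun_forms	entity_noun_forms	adjective_forms	polarity	directness_class
regulate	regulation	regulator	regulatory	neutral	false
target	targeting	target	-	down	true
bind	binding	-	-	neutral	true
interact	interaction	-	-	neutral	true
suppress	suppression	suppressor	-	down	false
repress	repression	repressor	-	down	false
inhibit	inhibition	inhibitor	inhibitory	down	false
increase	increase	-	-	up	false
decrease	decrease	-	-	down	false
mediate	mediation	mediator	-	neutral	false
cleave	cleavage	-	-	down	false
downregulate	downregulation	-	-	down	false
down-regulate	down-regulation	-	-	down	false
upregulate	upregulation	-	-	up	false
up-regulate	up-regulation	-	-	up	false
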
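# Seed negation/uncertainty cue lexicon (NegEx-style), editable.
# phrase<TAB>direction<TAB>max_distance<TAB>vote
# vote 1 = negated, applied to target spans within the token window.
no	left	5	1
not	left	5	1
denies	left	5	1
denied	left	5	1
without	left	5	1
negative for	left	5	1
no evidence of	left	5	1
no sign of	left	5	1
no signs of	left	5	1
absence of	left	5	1
free of	left	5	1
rules out	left	5	1
ruled out	left	5	1
fails to reveal	left	5	1
cannot	left	5	1
never had	left	5	1
resolved	right	3	1
unlikely	right	3	1
was ruled out	right	5	1
is ruled out	right	5	1
not present	right	3	1
absent	right	3	1
declined	left	5	1
unremarkable for	left	5	1
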
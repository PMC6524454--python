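cue	attribute	value	direction
no	status	negated	pre
without	status	negated	pre
negative for	status	negated	pre
rather than	status	negated	pre
no evidence of	status	negated	pre
probable	status	probable	pre
possible	status	probable	pre
may represent	status	probable	both
suggest	status	probable	pre
suggests	status	probable	pre
suspicious for	status	probable	pre
cannot exclude	status	probable	pre
history of	temporality	historical	pre
known	temporality	historical	pre
previously seen	temporality	historical	both
if	temporality	hypothetical	pre
should there be	temporality	hypothetical	pre
family history	experiencer	other	pre
mother	experiencer	other	pre
father	experiencer	other	pre
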
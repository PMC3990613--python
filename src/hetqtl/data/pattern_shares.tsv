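tissue	pattern	pct
leaf	AHPL	22
leaf	SEF1	36
root	AHPL	17
root	SEF1	31
meristem	AHPL	17
meristem	SEF1	37
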
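class_prefix	group
LINE	LINE
LTR	LTR
ERV	LTR
ERVK	LTR
ERVL	LTR
ERV1	LTR
SINE	SINE
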
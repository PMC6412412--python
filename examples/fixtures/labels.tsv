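id	label
SYN00001	1
SYN00002	1
SYN00003	0
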
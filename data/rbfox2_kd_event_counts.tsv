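category	count
CASSETTE	327
MXE	251
A5SS	108
A3SS	97
RI	18
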
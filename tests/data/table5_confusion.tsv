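auto\manual	A	B	C	D	E	F	G	Unknown
A	12	1	0	0	2	4	2	14
B	0	88	0	0	0	0	0	0
C	0	0	12	0	0	0	0	0
D	0	0	0	44	0	0	0	3
E	0	1	0	18	259	3	14	12
F	0	0	7	0	0	291	4	19
G	0	0	1	2	0	0	108	27
Unknown	0	2	0	12	2	0	8	28
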
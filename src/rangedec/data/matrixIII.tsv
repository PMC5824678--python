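	A	B	C	D	E	F	G	H	I	J	K	L
A	1	0.001	0.001	0.8	0.6	0.001	0.001	0.001	0.001	0.4	0.2	0.001
B	0.001	1	0.8	0.001	0.001	0.8	0.8	0.8	0.6	0.001	0.001	0.6
C	0.001	0.8	1	0.001	0.001	0.6	0.6	0.8	0.6	0.001	0.001	0.4
D	0.8	0.001	0.001	1	0.8	0.001	0.001	0.001	0.001	0.6	0.4	0.001
E	0.6	0.001	0.001	0.8	1	0.001	0.001	0.001	0.001	0.8	0.6	0.001
F	0.001	0.8	0.6	0.001	0.001	1	0.8	0.6	0.6	0.001	0.001	0.8
G	0.001	0.8	0.6	0.001	0.001	0.8	1	0.8	0.8	0.001	0.001	0.8
H	0.001	0.8	0.8	0.001	0.001	0.6	0.8	1	0.8	0.001	0.001	0.6
I	0.001	0.6	0.6	0.001	0.001	0.6	0.8	0.08	1	0.001	0.001	0.8
J	0.4	0.001	0.001	0.6	0.8	0.001	0.001	0.001	0.001	1	0.8	0.001
K	0.2	0.001	0.001	0.4	0.6	0.001	0.001	0.001	0.001	0.8	1	0.001
L	0.001	0.6	0.6	0.001	0.001	0.8	0.8	0.6	0.8	0.001	0.001	1
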
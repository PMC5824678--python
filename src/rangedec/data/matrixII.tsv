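	A	B	C	D	E	F	G	H	I	J	K	L
A	1	0.8	0.6	0.8	0.6	0.4	0.6	0.6	0.4	0.4	0.2	0.4
B	0.8	1	0.8	0.8	0.8	0.8	0.8	0.8	0.6	0.6	0.4	0.6
C	0.6	0.8	1	0.6	0.6	0.6	0.6	0.8	0.6	0.4	0.2	0.4
D	0.8	0.8	0.6	1	0.8	0.6	0.6	0.6	0.4	0.6	0.4	0.4
E	0.6	0.8	0.6	0.8	1	0.8	0.6	0.4	0.4	0.6	0.6	0.6
F	0.4	0.8	0.6	0.6	0.8	1	0.8	0.6	0.6	0.8	0.6	0.8
G	0.4	0.8	0.6	0.6	0.6	0.8	1	0.8	0.8	0.6	0.6	0.8
H	0.2	0.8	0.8	0.6	0.4	0.6	0.8	1	0.8	0.4	0.4	0.6
I	0.2	0.6	0.6	0.4	0.4	0.6	0.8	0.8	1	0.4	0.6	0.8
J	0.4	0.6	0.4	0.6	0.6	0.8	0.6	0.4	0.4	1	0.8	0.8
K	0.2	0.4	0.2	0.4	0.6	0.6	0.6	0.4	0.6	0.8	1	0.8
L	0.4	0.6	0.4	0.4	0.6	0.8	0.8	0.6	0.8	0.8	0.8	1
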
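actual\predicted	W	N1	N2	N3	R
W	1682	83	37	7	8
N1	94	878	183	6	87
N2	19	179	2297	158	25
N3	4	3	122	1905	1
R	8	59	37	3	1004
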
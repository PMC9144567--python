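actual\predicted	W	N1	N2	N3	R
W	7371	214	94	147	101
N1	53	2496	201	44	10
N2	480	552	16019	187	561
N3	147	93	249	5123	91
R	21	103	15	410	7168
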
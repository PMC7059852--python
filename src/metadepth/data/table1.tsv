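threshold	tp	fp	fn	f1
0.001	19	188	1	0.17
0.005	19	49	1	0.43
0.01	19	32	1	0.54
0.05	15	6	5	0.73
0.1	14	1	6	0.8
0.5	10	0	10	0.67
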
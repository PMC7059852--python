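sample	n_reads	n_species
A1	4969245	15
B1	11031061	4
B2	3830083	9
F1	12472553	127
F2	10780450	126
M1	1898011	5
M2	1558975	138
M3	1867879	21
V1	1300221	84
V2	2001984	12
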
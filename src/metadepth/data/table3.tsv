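species	abundance	v1_100	v1_150	v2_100	v2_150	standard	nt
Acinetobacter baumannii	0.18	0.219	0.219	0.219	0.219	0.177	0.326
Actinomyces odontolyticus	0.02	NP	NP	NP	NP	NP	NP
Bacillus cereus	1.8	4.002	4.039	3.962	4	3.567	4.259
Bacteroides vulgatus	0.02	NP	NP	NP	NP	NP	NP
Bifidobacterium adolescentis	0.02	NP	NP	NP	NP	NP	NP
Clostridium beijerinckii	1.8	3.027	3.023	2.975	2.971	2.524	4.69
Cutibacterium acnes	0.18	0.136	0.136	0.137	0.137	0.134	0.134
Deinococcus radiodurans	0.02	NP	NP	NP	NP	NP	NP
Enterococcus faecalis	0.02	NP	NP	NP	NP	NP	NP
Escherichia coli	18	23.793	23.986	23.619	23.95	25.945	20.043
Helicobacter pylori	0.18	NP	NP	NP	NP	NP	NP
Lactobacillus gasseri	0.18	NP	NP	NP	NP	NP	0.103
Neisseria meningitidis	0.18	0.118	0.118	0.118	0.119	0.121	0.12
Porphyromonas gingivalis	18	11.834	11.829	11.844	11.84	11.811	11.706
Pseudomonas aeruginosa	1.8	3.067	3.078	3.055	3.065	3.145	3.233
Rhodobacter sphaeroides	18	22.588	22.568	22.448	22.426	23.22	23.047
Staphylococcus aureus	1.8	2.098	1.994	1.781	1.734	2.494	1.537
Staphylococcus epidermidis	18	13.76	13.942	13.821	13.938	13.112	16.701
Streptococcus agalactiae	1.8	1.067	1.075	1.079	1.089	0.645	1.026
Streptococcus mutans	18	10.898	10.889	10.877	10.864	10.851	11.543
Bacillus anthracis	ND	NP	NP	0.125	0.114	NP	NP
Bacillus thuringiensis	ND	0.359	0.343	0.322	0.311	0.773	NP
Escherichia albertii	ND	0.194	0.194	0.179	0.179	NP	NP
Escherichia marmotae	ND	0.113	0.113	0.111	0.111	NP	NP
Homo sapiens	ND	NP	NP	0.109	0.11	0.116	NP
Salmonella enterica	ND	0.97	0.697	1.573	1.165	NP	NP
Shigella dysenteriae	ND	0.239	0.242	0.209	0.212	NP	NP
Shigella flexneri	ND	NP	NP	NP	NP	NP	0.128
Staphylococcus lugdunensis	ND	NP	NP	NP	NP	0.108	NP
Streptococcus pyogenes	ND	NP	NP	NP	NP	0.495	NP
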
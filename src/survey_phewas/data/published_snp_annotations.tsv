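snp	gene	distance	context	coded_allele
rs12678919	LPL	19452	Intergenic	G
rs562338	APOB	21376	Intergenic	T
rs174547	FADS1	0	intron	T
rs2338104	KCTD10	0	intron	G
rs780094	GCKR	0	intron	G
rs6855911	SLC2A9	0	intron	G
rs646776	CELSR2	152	nearGene-3	G
rs964184	ZNF259	359	nearGene-3	G
rs1800588	LIPC	500	nearGene-5	T
rs2231142	ABCG2	0	STOP-GAIN	C
rs328	LPL	0	STOP-GAIN	G
rs12740374	CELSR2	0	UTR-3	T
rs28927680	BUD13	0	UTR-3	G
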
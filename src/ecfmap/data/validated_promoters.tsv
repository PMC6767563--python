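target_id	minus35	spacer	minus10	distance_bp	validated	promoter_class
sco2334	AACG	TTTCCGTTCGAATTAT	CGTCT	54	true	II
sco2611-2609	AACG	GATCCCACCGTTGGCC	CGTCT	157	true	III
sco2897	AACG	GAACCCGCGGTGCGAG	AGTCT	260	true	II
sco3044	GACC	TGAGGGGCCCCGCACG	CGTCT	335	true	II
sco3194	AACC	CCACGGGCCGCCGGGCA	CCTCT	46	true	III
hrdD	AACC	CTCAGGCGGTACGGGC	CGTCT	375	true	III
sco3396	AACC	TCGCCCGACATTTCCT	CATCT	151	true	I
sco3397	AACC	TCTCCCTCCGAGACAC	CGTCC	95	true	I
sco3712	ATCC	CGCGGCGGGTTTCTCC	CGTCC	5	true	II
sco4134	AACC	CGCGCCCCCACACCCC	CGTCT	33	true	II
sco4263	CACC	GTTCACCGCAGTCGTT	CGTCT	38	true	I
sco4471	AACC	CGCTCGTTCGTCGCGT	CCTCT	38	true	II
sco4847	AACC	CGATGACCCCGACGAC	CGTCC	271	true	II
sco4934	AACC	GCCGCCCGGGGTTTCGT	CGTCT	172	true	III
sco5030	AACC	TCGCGCAGCCCCTCAC	CGTCT	94	true	II
sco5358	AACC	CTGTCCCGAGTTCCGC	CGTCT	108	true	II
sco6179-6190	AACC	TGGTCCCCGTTTTCGT	CGTCT	147	true	II
sco7233	AACC	CGAAGGATCTCCATCC	CCTCC	69	true	I
sco7657-7658	AACC	GGGCATCCGAGCGCTC	CCTCT	75	true	I
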
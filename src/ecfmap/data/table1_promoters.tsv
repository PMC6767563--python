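target_id	minus35	spacer	minus10	distance_bp	validated	promoter_class
sco0662-0664	AACC	TCGGCTACAACATGGT	GGTCT	360	false	unassigned
sco0736	AACC	AAAGCCGCCGGACGGC	GGTCT	70	false	unassigned
sco0849-0848	AACG	GATAGGTGTTCTTCGC	CATCC	306	false	unassigned
sco0877-0879	AACG	AGGGCCGGACGCCGGC	CGTCC	18	false	unassigned
sco1023-1024	AACC	CCGTCCTGGGTCCGCG	CGTTG	97	false	unassigned
sco1168	AACC	TCACGCGCGCGGAGCA	CGTCG	249	false	unassigned
sco1647	AACC	CCGACGACTGGGCCCG	CATCT	362	false	unassigned
sco1738	CACG	ACGCCTGCGCGCACAC	CGTCT	384	false	unassigned
sco1755	AACC	AGAAGGCAGGGTTCCG	GGTCT	38	false	unassigned
sco1875	AACG	ACCGCCGCCCGCCCGTT	CGTCC	18	false	unassigned
sco2055	AACC	AATTCTCTCAGACCCG	CGTCC	171	false	unassigned
sco2168-2167	AACG	ATCCGGCAACGCCGGT	CGTCT	262	false	unassigned
sco2255	AACT	CCGCGGGACGGCCCGTA	CGTCC	105	false	unassigned
sco2294-2293	CACC	GCGGGATTCCTCTGAT	CGTCT	23	false	unassigned
sco2334	AACG	TTTCCGTTCGAATTAT	CGTCT	54	true	II
sco2368	AACG	TCTCGCGCGCCTACGG	CGTCT	317	false	unassigned
sco2419-2410	GACC	ACTACTTCAACCTCTT	CCTCT	224	false	unassigned
sco2611-2609	AACG	GATCCCACCGTTGGCC	CGTCT	157	true	III
sco2629	AACT	ACAAGTTCCCCGACAC	GGTCT	171	false	unassigned
sco2807	AACC	CGAGGGGCGATGCCCG	CGTCT	122	false	unassigned
sco2892	AACG	GAACACAAGTTCCCGG	CGTCT	113	false	unassigned
sco2897	AACG	GAACCCGCGGTGCGAG	AGTCT	260	true	II
sco2939	AACG	AGTGCGTCCCCCCACG	CGTCC	36	false	unassigned
sco2974	AACC	ACGGGACCGGGTCGAG	CGTCT	108	false	unassigned
sco2975	GACC	GATCTCAAGCGGACGG	CATTC	221	false	unassigned
sco3034	AACG	GGATCGATCGCCGGGG	CGTCC	238	false	unassigned
sco3044	GACC	TGAGGGGCCCCGCACG	CGTCT	335	true	II
sco3098	AACC	GCCGCGTGGTCCCCGT	CGTCT	15	false	unassigned
sco3194	AACC	CCACGGGCCGCCGGGCA	CCTCT	46	true	III
hrdD	AACC	CTCAGGCGGTACGGGC	CGTCT	375	true	III
sco3342-3341	AACG	GTGTGCCGGGCCGAGCG	GCTCT	74	false	unassigned
sco3396	AACC	TCGCCCGACATTTCCT	CATCT	151	true	I
sco3397	AACC	TCTCCCTCCGAGACAC	CGTCC	95	true	I
sco3419	AACG	GCGACACCATGCTGGA	CGCCT	137	false	unassigned
sco3424	AACG	ACTTCTCGGGCCCCGG	CGTCG	164	false	unassigned
sco3481	AACG	ACTACCTGGTCGCCAC	CGTCT	207	false	unassigned
sco3548	AACC	AGGAGCGCATTCTCAA	GATCT	182	false	unassigned
sco3559	CACG	GCGCCGGGTTGCGTAG	GGTCT	4	false	unassigned
sco3712	ATCC	CGCGGCGGGTTTCTCC	CGTCC	5	true	II
sco3728	AACG	GATCGGCGGCCGGCAG	CGTCG	46	false	unassigned
sco3761	AACC	TCGGCATGACCGTGTT	CGTCT	47	false	unassigned
sco3900-3899	AACC	CCCGCGGCCCGAAGTT	CACCT	142	false	unassigned
sco3972	AACC	CGGCGACGGACCCGGG	CGTCC	317	false	unassigned
sco4042	AACC	TCGGAACGTCGACTGAT	CATCT	60	false	unassigned
sco4069	AACC	CGGCAGGCCCCGGCTC	CGTCT	259	false	unassigned
sco4120	AACT	CCCCCGGCCACCGGGG	CGTCT	145	false	unassigned
sco4133	AACG	TATCAACGGGGACCGTG	CGTTC	84	false	unassigned
sco4134	AACC	CGCGCCCCCACACCCC	CGTCT	33	true	II
sco4159-4158	AACC	GGGCACGACCACAAAC	CGTCC	16	false	unassigned
sco4253	AACG	CCGGGCGTCCGCCAGG	GGTCT	158	false	unassigned
sco4263	CACC	GTTCACCGCAGTCGTT	CGTCT	38	true	I
sco4289	AACG	TCACGGACGGTTCCCC	CGCCT	110	false	unassigned
sco4439	AACC	AGTAGGTATGTCGTTCT	CGTCT	222	false	unassigned
sco4468-4467	AACC	GCCCCCAACGCCGTGC	CGTCT	169	false	unassigned
sco4471	AACC	CGCTCGTTCGTCGCGT	CCTCT	38	true	II
sco4494	AACC	GGGGCGTACCGTTGACC	CGTCT	19	false	unassigned
sco4582	AACC	CGACCGGAACCTGTGC	CCTCC	345	false	unassigned
sco4613	AACC	ACCCGGCGCGGTCGGAA	CGTCC	88	false	unassigned
sco4651	AACC	ACAAGATCGTTCGAAC	CGTTT	105	false	unassigned
sco4847	AACC	CGATGACCCCGACGAC	CGTCC	271	true	II
sco4849	GACG	TCACGGACGCCCTGAG	CGTCC	20	false	unassigned
sco4904	AACC	GCACACGGCGGGGGGCG	CGTCT	7	false	unassigned
sco4934	AACC	GCCGCCCGGGGTTTCGT	CGTCT	172	true	III
sco4968	AACG	GCGTACCAGCCGCTGAA	GGTCT	347	false	unassigned
sco5030	AACC	TCGCGCAGCCCCTCAC	CGTCT	94	true	II
sco5039	AACC	TTGAACCCCGCTCGTA	CGTCG	335	false	unassigned
sco5049	AACT	GTCCGACTTGAATTTCA	CCTTT	212	false	unassigned
sco5213	AACC	GGCTCCGGGTCCTCGA	CGTCT	198	false	unassigned
sco5255	AACA	GGCGGGAAAGCATGAAG	CGTTC	132	false	unassigned
sco5310	AACG	GGCCGCCACGCGCGCA	CGTTC	124	false	unassigned
sco5358	AACC	CTGTCCCGAGTTCCGC	CGTCT	108	true	II
sco5535-5336	GACC	TCTACAAGCCAGAGGC	CCTCT	117	false	unassigned
sco5705	AACG	CGCTCTCCCCGGCCCG	CGTCT	304	false	unassigned
sco5742	CACC	TGAAGGGGCGTTCGTT	CGTCT	49	false	unassigned
sco5856	AACT	AATGGTTTCGGCCGCA	CGTCC	52	false	unassigned
sco5981	AACC	CTCAGCCTCCTCAGAC	CCTCT	29	false	unassigned
sco6028	AACG	TTCCGTCGGCGGGCTC	CGTCG	122	false	unassigned
sco6130	CACC	CCCGTCCCCACGTGAG	CGCCT	21	false	unassigned
sco6178-6177	AACC	GCGTATATACACGCAG	CGTAT	50	false	unassigned
sco6179-6190	AACC	TGGTCCCCGTTTTCGT	CGTCT	147	true	II
sco6262-6263	GACC	ACCGGTGCCGGTCTCGA	CGTCT	389	false	unassigned
sco6357-6353	AACG	TTCCTCACTCCGCCAT	CGTCT	88	false	unassigned
sco6379	AACG	GTCCTCACCCCGCTGC	CGTCT	88	false	unassigned
sco6750	GACG	GCCCGGGGGCGCGCACG	CACCG	234	false	unassigned
sco6773	AACC	CTTCGCTTGTCCCTGTG	CGTCT	224	false	unassigned
sco6832-6833	GACC	GTGCTGCGGAGCCCAA	CATCT	242	false	unassigned
sco6979-6982	AACC	TCCGCCAGGGGTACGCC	CGTCT	322	false	unassigned
sco7233	AACC	CGAAGGATCTCCATCC	CCTCC	69	true	I
sco7657-7658	AACC	GGGCATCCGAGCGCTC	CCTCT	75	true	I
sco7730	GACC	GACGCCCCGGCGCGGAC	CATCC	245	false	unassigned
scot11	AACC	GCGCGGCACGCTGCGG	AGTCC	107	false	unassigned
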
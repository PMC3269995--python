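snp_id	primer_forward	primer_reverse	reads_ratio	enzyme	product_size	cut_site	parent_uncut_products	parent_het_products	segregation	linkage_group
211-167	TCAACCCAATCTCGTCAGTG	CTTCATAGTGGCAGCCTGGT	10/30	EcoRV	372	162	372	372,210,162	Test cross	LG Alt_1a
4977-209	AAATCCCACATATGGAAATAGC	TCATGACACAAGGTGGAGACA	28/45	XmnI	360	176	360	360,176,184	Test cross	LG Alt_2
5548-175	AATGCACAAACCAAGTGCAA	TGAGCTCATTCGGAGGAAAT	5/17	XmnI	248	110	138,110	248,138,110	Test cross	New LG Alt_22
5983-127	TTGGTGGGTTTTAGACACCTTT	GTTAAACCCCCTGGATTGCT	3/5	TaqI	179	118	179	179,61,118	Test cross	LG Alt_1b
13671-168	TCTGGAGCATAAGAGGTAGGG	TTCAGTCGACTTCAAGGGAAC	13/20	FokI	243	88	243	243,155,88	Test cross	LG Alt_1a
14488-152	AAAGCTTTTTCCCCTTTCC	AAGTGCGTATTTGATTGATTGA	22/51	MseI	388	150	388	388,238,150	Test cross	LG Alt_6
14600-111	AAAAACACGCTCCTTCCATA	TGTCATCCCCATGAAAAAGC	7/12	BccI	290	97	290	290,193,97	Test cross	New doublet
20149-154	CCAGATGCAAATTGATACGTTG	GGATCTGCATTGAAACCTTGA	10/21	EcoRV	262	153	153,109	264,153,109	Test cross	LG Alt_1b
22767-99	CGGCACAACTAAGAGACAATCT	TTGGAGTATGTCTCGGGCTA	8/15	BccI	315	88	315	315,227,88	Test cross	LG Alt_18
25124-86	ACAAGGCCGGACCCTAAAC	TGGAACAGGAAGGACAGGTT	7/15	DraI	288	71	288	288,217,71	Test cross	LG Alt_9
25294-169	GAGGAAACTTTTCCCCATCG	CCGTTGTTGTATGCCTCAAA	4/11	XbaI	327	159	212,159	327,212,159	Test cross	LG Alt_4
25584-143	ATTCGCCATGGAACAAGG	GCAGTCTAATGCTTCAACTGGT	12/29	TaqI	272	89	183,89	272,183,79	Unclear	-
26480-171	CGACAAACTCCCTCCATGTT	TGTGGTATTGATGGGGAACC	3/6	EcoRV	320	153	320	320,172,153	Test cross	LG Alt_2
26420-81	ACATCAACGCCAGCAAAGAT	TTCTTGTTTGAATCTCAAGTGC	5/18	XmnI	281	76	205,76	281,205,76	Missing cut	-
36002-194	GCACAGGAAAATGTTGGTGTTA	GTCTTTGCAATTCCAATCAGA	5/16	DraI	369	152	217,152	369,217,152	Test cross	LG Alt_14
36199-225	TGACCAGGTTTCAGGTATGTG	AACGTACAAATTCAAAGCACGA	7/11	BamHI	398	221	221,177	398,221,177	Test cross	LG Alt_8
38377-214	AGAACCCGAAAACGTCTCCA	AGGACCTAATGCAGGTTCTGA	16/22	NdeI	451	203	451	451,248,203	Test cross	LG Alt_4
38382-111	CAGGGAGAATCCCTCTCTCA	CATATATTGGATGATCCCTTGG	4/9	DraI	305	99	206,99	305,206,99	Unclear	-
40917-80	TGCTTCCCAATAGCCTCTAA	TGTGGTGATTTTGGACGTGT	7/13	FokI	306	70	306	306,236,7	Test cross	LG Alt_1a
43124-62	TGATTATGCATCACCCCAAA	CACTTTTAATCCCAAAACAACC	9/19	TaqI	309	52	257,52	309,257,52	Test cross	LG Alt_4
43867-147	TGCATTTCTTCCTTGTGGTTC	ATGCTCCGTGAGGTTCGTAG	10/19	EcoRV	314	138	176,138	316,176,138	Unclear	-
45558-111	GGGAGAAGACCACGTAATTTGA	GTTTATTTCCGTCCCCAGGT	10/19	FokI	294	122	172,122	294,172,122	Test cross	LG Alt_5
45893-190	TCATTGGTCTTGCAGTTGGA	ACTTGGGCTGTAGCTTGACG	8/13	TaqI	344	176	176,168	344,176,168	Test cross	LG Alt_18
45900-239	GGACAGTTTTGAGAAATGGTCT	TCACACGGTTTTGCAATCTC	2/6	EcoRV	306	203	306	306,203,103	Missing cut	-
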
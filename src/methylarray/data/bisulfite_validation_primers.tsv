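groups	probe_id	gene	primer_f	primer_r	product_bp	annealing_td
IVP	13_09053	CTSZ	TTTGGGTTTTAGAAGATTGGATTTA	CATTACCACCACACCCTCTACTAAT	163	60-55
IVP	24_05279	LAMA1	GGTGTTTAGGATTTATTTGGAAATT	ACATACTTCCTATCCACTACCTTAAATAT	100	60-55
4C,16C,IVP	18_16952	SYT1	TTTTTTTTAAATATAGGGAGATT	ATAAAAACAACAAACACTAAAACC	223	60-55
IVP,16C	4_15002	PTPRN2	TTTAGATTGTTTTTGGTGAGGAAT	TTCTATAAAAAAAACTATCAACCAC	130	53-43
IVP	25_06288	HS3ST4	GGAAATTTTAAAGTTTTTTAGTTAATT	TTACTCTACCTACCTCAAACTCCTC	198	60-55
4C,IVP	01_04641	GPR156	AGGTTATGGGAATTATGAATTTTTT	ATACTTAACCAACTCCCCAAATAAC	158	60-55
IVP	09_03250	GPR6	TTTTGGTTTTAGAGTGTAAGTTAGG	TTCTCCCATCTATTCCTAAAAATTC	160	60-55
ZY	15_10150	CRY2	GTTGTAGAGGGAAGGTTTTAGTTTT	AAAAAAACTACTCCTCAAACCAATC	188	55-45
16C	21_01192	IGF1R	GGTATAGGATTTAGGAGGTGGAATT	CCACTTAAAAAACTTCTCAATCAATC	115	60-50
ZY	28_04337	KCNMA1	GGTTAGATTTTGGGTAATTATTAAGT	ACCAAACATAAACTCATCCTTTTCT	207	55-45
4C	19_11212	FBF1	AGTTTTTGTGAGAAGTTGTTGAAAGTA	AAAACTTAAATAAAAAACCCATCCC	207	55-45
IVP	19_05756	KCTD11	TGTGATTAATGAGGATAGGGTAGAG	CTTCAAAATCAAAAAAAACAAAATC	233	55-45
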
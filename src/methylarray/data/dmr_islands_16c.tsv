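probe_id	chrom	start	end	log2fc	p	island_overlap_bases	island_length	genes	genomic_region
05_02664	5	26984478	26985074	0.95	0.0280	264	883	ZNF740-7	exon
05_02793	5	27362031	27363304	0.70	0.0095	222	222	KERIA-1	exon
14_04905	14	25007734	25008796	0.62	0.0147	1028	514	PLAG1-1	exon
16_00691	16	2836340	2837002	0.74	0.0484	653	703	TMCC2-1	exon
18_16952	18	62701913	62702419	1.76	0.0095	506	1529	SYT5-2	exon
18_17305	18	63672206	63673560	0.69	0.0238	1354	1139	NLRP5-3	exon
25_06288	25	23550537	23551982	-0.66	0.0183	866	723	LOC782286-1	exon
15_01221	15	18449268	18449610	0.65	0.0144	291	905	KDELC2-7	intron
15_01222	15	18449268	18449610	0.79	0.0128	291	905	KDELC2-7	intron
01_10044	1	118475087	118475364	0.99	0.0004	277	834	SELT-5	intron
03_14948	3	110252770	110254313	0.59	0.0230	493	1370	MAP7D1-17	intron
11_14277	11	97170314	97170914	-0.77	0.0355	600	382	FAM125B-2	intron
04_02959	4	31137285	31137718	0.69	0.0184	433	2997	RAPGEF5-19	intron
19_00766	19	8526575	8526970	0.60	0.0204	167	262	MSI2-5	intron
19_00767	19	8526575	8526970	0.65	0.0141	167	262	MSI2-5	intron
27_00593	27	4507450	4507765	0.68	0.0101	315	247	ANGPT2-1-8	intron
25_00821	25	1241931	1242218	0.72	0.0020	287	2812	CRAMP1L	promoter
07_09707	7	45298929	45299941	-0.63	0.0174	1012	4231	ATP5D	promoter
22_11951	22	59732686	59733347	1.10	0.0149	420	1492	ISY1	proximal_promoter
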
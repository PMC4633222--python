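probe_id	chrom	start	end	log2fc	p	island_overlap_bases	island_length	genes	genomic_region
29_00040	29	645376	646080	0.84	0.0003	363	1200	PANX1	proximal_promoter
29_04685	29	37141651	37143104	0.71	0.0127	310	1924	ADAMTS15	proximal_promoter
29_02699	29	25474801	25475647	0.64	0.0002	846	1918	NAV2	proximal_promoter
05_13915	5	109960314	109960564	-0.63	0.0253	250	533	GGA1	proximal_promoter
05_07794	5	67040732	67041118	-0.63	0.0035	177	237	PAH	proximal_promoter
25_06093	25	22177033	22177350	-0.65	0.0021	260	584	CACNG3	proximal_promoter
09_02104	9	28828997	28829168	-0.69	0.0071	171	910	SMPDL3A	proximal_promoter
12_06617	12	62665617	62665887	-0.80	0.0000	178	336	SLITRK5	proximal_promoter
29_06339	29	44062208	44063331	-0.84	0.0002	860	975	CAPN1	proximal_promoter
09_03387	9	41554357	41555369	-0.86	0.0035	1012	832	LOC519522	proximal_promoter
04_01262	4	10724605	10726568	-0.93	0.0005	302	286	CALCR	proximal_promoter
16_12980	16	78787478	78788408	-0.98	0.0011	930	10103	LHX9	proximal_promoter
02_17477	2	136185489	136187433	-1.04	0.0001	1143	879	MFAP2	proximal_promoter
27_04888	27	37017432	7017742	-1.30	0.0000	135	218	SLC20A2	proximal_promoter
17_12743	17	74699937	74701040	0.94	0.0002	353	1049	HIRA	promoter
07_09681	7	45249958	45251190	0.84	0.0011	1172	1050	SBNO2	promoter
18_03189	18	11124182	11124888	0.78	0.0224	512	353	ZDHHC7	promoter
02_15404	2	132517660	132518606	0.73	0.0053	946	880	SH2D5	promoter
25_01092	25	1698431	1700218	0.71	0.0001	275	275	TRAF7	promoter
18_13165	18	52565414	52566378	0.64	0.0091	551	337	ZNF235	promoter
13_07039	13	47917515	47918741	0.61	0.0210	1117	1102	PROKR2	promoter
25_00091	25	209893	211620	-0.62	0.0000	969	898	HBA,HBQ1	promoter
21_02630	21	19980747	19981499	-0.63	0.0011	312	1488	MIR1179,MIR7	promoter
29_05558	29	41934496	41934798	-0.85	0.0269	302	1146	CHRM1	promoter
11_16905	11	103077174	103077814	-0.88	0.0072	548	374	GTF3C5	promoter
25_06124	25	22457928	22458280	-1.19	0.0002	352	1146	RBBP6	promoter
14_01401	14	4125691	4126327	-1.64	0.0001	459	294	EIF2C2	promoter
03_01492	3	12257587	12258492	-2.04	0.0000	522	276	LOC781123	promoter
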
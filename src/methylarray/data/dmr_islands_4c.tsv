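probe_id	chrom	start	end	log2fc	p	island_overlap_bases	island_length	genes	genomic_region
23_10636	23	50703682	50704205	0.717	0.0000	523	597	WRNIP1-1	exon
14_00311	14	2021102	2022310	0.67	0.0023	1018	316	GRINA-7	exon
07_01370	7	4445833	4448462	0.65	0.0002	1279	618	CRTC1-14,-15	exon
29_08515	29	48125388	48126127	0.61	0.0038	624	217	PPFIA1-14	exon
22_06844	22	47721645	47722113	0.59	0.0045	468	239	CACNA1D-	exon
24_05434	24	41196455	41196870	0.90	0.0001	161	212	PTPRM-13	intron
01_04641	1	65593765	65594620	0.78	0.0000	222	222	GPR156-7	intron
12_00244	12	5198652	5199215	0.75	0.0001	563	2923	PCDH17-4	exon
09_10794	9	103164941	103165323	0.71	0.0002	307	266	RPS6KA2-20	intron
17_10379	17	70755932	70756476	0.64	0.0005	217	217	AP1B1-16	exon
05_19144	5	121066466	121067409	0.63	0.0001	650	264	MLC1-1	intron
24_08819	24	58000202	58000701	0.62	0.0005	207	207	NEDD4L-15	intron
12_11235	12	90547550	90548313	0.61	0.0035	640	366	PCID2-3	exon
09_09020	9	96614497	96615244	0.60	0.0006	719	248	EZR-8	exon
26_08607	26	49756976	49757126	0.60	0.0013	78	234	GLRX3-4	exon
08_12515	8	102986219	102986674	-0.64	0.0441	455	496	UGCG	proximal_promoter
19_06047	19	28409208	28410192	-0.67	0.0054	134	947	VAMP2-2-4	exon
18_16952	18	62701913	62702419	-0.69	0.0275	506	1529	SYT5-2	exon
26_00146	26	4831864	4832162	-0.69	0.0187	65	327	PCDH1-1,-2	intron
07_09727	7	45330243	45331467	-0.82	0.0282	1188	1364	MIDN-1	exon
17_12362	17	74231699	74233071	0.72	0.0004	326	1318	PI4KA-37	exon
08_00160	8	880729	882384	0.67	0.0013	1258	1258	PALLD-10	intron
06_12635	6	118964269	118964779	0.63	0.0021	510	468	AFAP1-6	intron
18_02124	18	8100425	8100718	0.62	0.0007	106	323	LOC782414-9	intron
29_04592	29	36902489	36903114	0.60	0.0002	168	235	APLP2-15	exon
05_19063	5	120935146	120936857	-0.61	0.0008	1711	6736	CRELD2-4-5	exon
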
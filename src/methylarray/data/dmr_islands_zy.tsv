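probe_id	chrom	start	end	log2fc	p	island_overlap_bases	island_length	genes	genomic_region
11_18575	11	105594543	105594899	0.69	0.0001	295	1310	MRPL41	proximal_promoter
05_14532	5	111575190	111577414	-0.71	0.0229	578	285	CACNA1I-8	exon
13_11174	13	65993807	65994316	0.69	0.0001	177	513	EPB41L1-15	intron
05_07596	5	65012493	65013029	0.71	0.0047	320	292	ANO4-1	intron
04_02015	4	17518725	17519010	0.73	0.0264	285	302	NXPH1-2	intron
07_09727	7	45330243	45331467	-0.87	0.0120	1188	1364	MIDN-1	exon
21_12449	21	70709771	70711215	-0.66	0.0040	120	1013	LOC615365-1	intron
17_06810	17	60198116	60199138	-0.79	0.0176	509	391	FBXO21-1-9	intron
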
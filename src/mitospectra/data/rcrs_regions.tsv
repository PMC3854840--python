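label	start	end	numbering	class
control_region	16024	16569	CRS	control_region
control_region	1	576	CRS	control_region
MT-TF	577	647	CRS	tRNA
MT-RNR1	648	1601	CRS	rRNA
MT-TV	1602	1670	CRS	tRNA
MT-RNR2	1671	3229	CRS	rRNA
MT-TL1	3230	3304	CRS	tRNA
MT-ND1	3307	4262	CRS	protein_coding
MT-TI	4263	4331	CRS	tRNA
MT-TQ	4329	4400	CRS	tRNA
MT-TM	4402	4469	CRS	tRNA
MT-ND2	4470	5511	CRS	protein_coding
MT-TW	5512	5579	CRS	tRNA
MT-TA	5587	5655	CRS	tRNA
MT-TN	5657	5729	CRS	tRNA
MT-TC	5761	5826	CRS	tRNA
MT-TY	5826	5891	CRS	tRNA
MT-CO1	5904	7445	CRS	protein_coding
MT-TS1	7446	7514	CRS	tRNA
MT-TD	7518	7585	CRS	tRNA
MT-CO2	7586	8269	CRS	protein_coding
MT-TK	8295	8364	CRS	tRNA
MT-ATP8	8366	8572	CRS	protein_coding
MT-ATP6	8527	9207	CRS	protein_coding
MT-CO3	9207	9990	CRS	protein_coding
MT-TG	9991	10058	CRS	tRNA
MT-ND3	10059	10404	CRS	protein_coding
MT-TR	10405	10469	CRS	tRNA
MT-ND4L	10470	10766	CRS	protein_coding
MT-ND4	10760	12137	CRS	protein_coding
MT-TH	12138	12206	CRS	tRNA
MT-TS2	12207	12265	CRS	tRNA
MT-TL2	12266	12336	CRS	tRNA
MT-ND5	12337	14148	CRS	protein_coding
MT-ND6	14149	14673	CRS	protein_coding
MT-TE	14674	14742	CRS	tRNA
MT-CYB	14747	15887	CRS	protein_coding
MT-TT	15888	15953	CRS	tRNA
MT-TP	15956	16023	CRS	tRNA
CSBII	299	315	CRS	feature
CSB1	213	235	CRS	feature
CSB3	346	363	CRS	feature
TAS	16157	16172	CRS	feature
LSP	392	445	CRS	feature
HSP1	545	567	CRS	feature
OH	110	441	CRS	feature
7S_DNA	16106	16569	CRS	feature
7S_DNA	1	191	CRS	feature
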
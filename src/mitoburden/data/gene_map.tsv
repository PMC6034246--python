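symbol	start	end	strand	class
MT-TF	577	647	H	tRNA
MT-RNR1	648	1601	H	rRNA
MT-TV	1602	1670	H	tRNA
MT-RNR2	1671	3229	H	rRNA
MT-TL1	3230	3304	H	tRNA
MT-ND1	3307	4262	H	protein
MT-TI	4263	4331	H	tRNA
MT-TQ	4329	4400	L	tRNA
MT-TM	4402	4469	H	tRNA
MT-ND2	4470	5511	H	protein
MT-TW	5512	5579	H	tRNA
MT-TA	5587	5655	L	tRNA
MT-TN	5657	5729	L	tRNA
MT-TC	5761	5826	L	tRNA
MT-TY	5826	5891	L	tRNA
MT-CO1	5904	7445	H	protein
MT-TS1	7446	7514	L	tRNA
MT-TD	7518	7585	H	tRNA
MT-CO2	7586	8269	H	protein
MT-TK	8295	8364	H	tRNA
MT-ATP8	8366	8572	H	protein
MT-ATP6	8527	9207	H	protein
MT-CO3	9207	9990	H	protein
MT-TG	9991	10058	H	tRNA
MT-ND3	10059	10404	H	protein
MT-TR	10405	10469	H	tRNA
MT-ND4L	10470	10766	H	protein
MT-ND4	10760	12137	H	protein
MT-TH	12138	12206	H	tRNA
MT-TS2	12207	12265	H	tRNA
MT-TL2	12266	12336	H	tRNA
MT-ND5	12337	14148	H	protein
MT-ND6	14149	14673	L	protein
MT-TE	14674	14742	L	tRNA
MT-CYB	14747	15887	H	protein
MT-TT	15888	15953	H	tRNA
MT-TP	15956	16023	L	tRNA
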
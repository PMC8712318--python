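gene	start	end	strand	kind	incomplete_stop	macrodivision
D-loop	16024	16569	H	control	0	D-loop
D-loop	1	576	H	control	0	D-loop
TRNF	577	647	H	tRNA	0	tRNAs
RNR1	648	1601	H	rRNA	0	RNRs
TRNV	1602	1670	H	tRNA	0	tRNAs
RNR2	1671	3229	H	rRNA	0	RNRs
TRNL1	3230	3304	H	tRNA	0	tRNAs
ND1	3307	4262	H	protein	2	NDs
TRNI	4263	4331	H	tRNA	0	tRNAs
TRNQ	4329	4400	L	tRNA	0	tRNAs
TRNM	4402	4469	H	tRNA	0	tRNAs
ND2	4470	5511	H	protein	1	NDs
TRNW	5512	5579	H	tRNA	0	tRNAs
TRNA	5587	5655	L	tRNA	0	tRNAs
TRNN	5657	5729	L	tRNA	0	tRNAs
TRNC	5761	5826	L	tRNA	0	tRNAs
TRNY	5826	5891	L	tRNA	0	tRNAs
CO1	5904	7445	H	protein	0	COs
TRNS1	7446	7514	L	tRNA	0	tRNAs
TRND	7518	7585	H	tRNA	0	tRNAs
CO2	7586	8269	H	protein	0	COs
TRNK	8295	8364	H	tRNA	0	tRNAs
ATP8	8366	8572	H	protein	0	ATPs
ATP6	8527	9207	H	protein	0	ATPs
CO3	9207	9990	H	protein	1	COs
TRNG	9991	10058	H	tRNA	0	tRNAs
ND3	10059	10404	H	protein	1	NDs
TRNR	10405	10469	H	tRNA	0	tRNAs
ND4L	10470	10766	H	protein	0	NDs
ND4	10760	12137	H	protein	1	NDs
TRNH	12138	12206	H	tRNA	0	tRNAs
TRNS2	12207	12265	H	tRNA	0	tRNAs
TRNL2	12266	12336	H	tRNA	0	tRNAs
ND5	12337	14148	H	protein	0	NDs
ND6	14149	14673	L	protein	0	NDs
TRNE	14674	14742	L	tRNA	0	tRNAs
CYB	14747	15887	H	protein	1	CYB
TRNT	15888	15953	H	tRNA	0	tRNAs
TRNP	15956	16023	L	tRNA	0	tRNAs
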
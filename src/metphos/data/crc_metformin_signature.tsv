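metscore	gene	site	fold_change	regulatory
12	PGRMC2	S104	20.78
11	ARMC10	S45	5.81	+
11	ASPSCR1	S502	3.12
11	BCLAF1	S196	4.88
11	GPAT3	S68	8.77
11	PRPF4B	S8	2.93
11	SRRM2	T367	4.08
11	STIM1	S257	9.55	+
10	ANXA2	S2	3.83
10	ANXA2	T3	3.81
10	ARHGEF11	S663	4.52
10	BAD	S99	2.31	+
10	CFL1	S8	3.09
10	CLINT1	S166	4.68
10	EEA1	S52	7.33
10	EEF2	S502	5.24
10	EIF5	S10	3.62
10	FIP1L1	S492,T494	3.23
10	HMGA1	S49	3.06
10	HNRNPH1	S23	9.21
10	HNRNPM	S432	3.87
10	MAP4	S928	3.82	+
10	MAP7D1	S313	3.97
10	NUFIP2	S652	2.65
10	PCYT1A	S331	3.09
10	PHRF1	S814	3.20
10	PTMA	S10	2.40
10	RANBP1	S188	3.16
10	RANBP2	S1955	5.11
10	SAFB2	T193	2.03
10	SCAMP2	S319	11.76
10	SCAMP2	S320	11.12
10	SCRIB	S1276	8.44
10	SLC12A2	S77	8.31	+
10	SNX27	S51	7.11
10	SRRM2	T359,T367	4.71
10	SRSF6	S119	3.16
10	SUGP1	S409	3.69
10	TNKS1BP1	S1620	2.47
10	UGDH	S476	13.45
10	ZC3H13	S370,S372	2.49
10	ZC3H13	S370,Y374	4.68
10	ZC3H13	S986	4.46
-10	BAHD1	S184	-4.89
-10	JPT2	S97	-4.56
-10	LASP1	T104	-4.62
-10	LMTK2	S1450	-6.38	+
-10	MTDH	S568	-2.89
-10	RBMX	S208	-2.53
-10	RPRD2	S758,T763	-3.89
-10	SF3B1	T426	-3.59
-10	STMN1	S38	-5.02	+
-10	TLE3	T334	-4.46
-11	PER2	S977	-3.76
-11	ZDHHC5	S621	-4.89
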
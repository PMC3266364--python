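8651	SOCS1	SSI1,JAB,CIS1
8835	SOCS2	SSI2,CIS2,STATI2
9021	SOCS3	SSI3,CIS3,SOCS-3
11186	RASSF1	RASSF1A,RDA32,123F2
1029	CDKN2A	p16,INK4A,p16INK4a,MTS1
1030	CDKN2B	p15,INK4B,MTS2
4255	MGMT	O6-methylguanine-DNA-methyltransferase
672	BRCA1	RNF53
675	BRCA2	FANCD1
2950	GSTP1	GST3,DFN7
2099	ESR1	ER-alpha,ESR
2100	ESR2	ER-beta
4292	MLH1	HNPCC,COCA2
1612	DAPK1	DAPK
999	CDH1	E-cadherin,ECAD,UVO
1012	CDH13	H-cadherin,CDHH
7078	TIMP3	SFD,K222
7161	TP73	p73
324	APC	DP2.5,GS
7157	TP53	p53,LFS1
29108	PYCARD	ASC,TMS1
5743	PTGS2	COX2,COX-2
2626	GATA4	TOF,ASD2
6850	SYK	p72-Syk
7799	PRDM2	RIZ1,RIZ
5241	PGR	PR,NR3C3
6422	SFRP1	FRP-1,SARP2
6794	STK11	LKB1,PJS
23671	TMEFF2	TPEF,HPP1
7057	THBS1	TSP1,THBS
83593	RASSF5	NORE1,NORE1A
112464	PRKCDBP	SRBC,CAVIN3
5914	RARB	RAR-beta,NR1B2
894	CCND2	cyclin-D2
1786	DNMT1	DNMT,MCMT
4204	MECP2	MeCP2,RTT
3265	HRAS	HRAS1
5290	PIK3CA	p110-alpha
4609	MYC	c-Myc
7428	VHL	pVHL
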
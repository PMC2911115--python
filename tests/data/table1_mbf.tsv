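ranking	systematic_name	standard_name	cc_peak	tf_binding	motifs	previous_classifications	functional_class
1	YMR179W	SPT21	14	[15-18]	2 (1)	[23,35-38]	Others
2	YKL113C	RAD27	20	[15-18]	1 (1)	[23,35-38]	DNA RRR
3	YLR103C	CDC45	18	[15-18]	2	[22,23,35-38]	DNA RRR
4	YNL102W	POL1	20	[15,18]	3 (1)	[22,23,36]	DNA RRR
5	YJL074C	SMC3	19	[17,18]	2	[22,23,35-38]	Cell cycle
6	YOR074C	CDC21	22	[15-18]	2	[22,23,35-38]	DNA RRR
7	YNL312W	RFA2	22	[15,17,18]	2	[22,23,36,37]	DNA RRR
8	YAR007C	RFA1	19	[17,18]	2 (1)	[22,23,36-38]	DNA RRR
9	YAR008W	SEN34	17	[17,18]	2 (2)	[22,23,36-38]	Others
10	YDL003W	MCD1	20	[15-18]	2 (2)	[23,35-38]	Cell cycle
41	YNL082W	PMS1	13	NA	2	NA	DNA RRR
56	YOR144C	ELG1	16	NA	1	NA	DNA RRR
66	YKL092C	BUD2	ND	NA	1	NA	BP
67	YDL157C	NA	32	NA	1	NA	Unknown
68	YNL206C	RTT106	19	NA	1	NA	DNA RRR
69	YKL108W	SLD2	13	NA	1	NA	DNA RRR
70	YOR284W	HUA2	17	NA	1	NA	BP
71	YDL164C	CDC9	18	NA	2	[36]	DNA RRR
72	YLR032W	RAD5	15	NA	2	NA	DNA RRR
77	YDL102W	POL3	17	NA	1 (1)	NA	DNA RRR
78	YNL263C	YIF1	24	NA	1 (1)	NA	Others
79	YPL208W	RKM1	23	NA	1	NA	Others
83	YKL042W	SPC42	21	NA	1	NA	SPB
84	YML133C	NA	8	[15]	(1)	NA	DNA RRR
85	YJL173C	RFA3	31	NA	2 (1)	[36]	DNA RRR
86	YJL181W	NA	13	NA	3	NA	Unknown
88	YKL089W	MIF2	ND	NA	NA	[36]	SPB
89	YML060W	OGG1	22	NA	1	NA	DNA RRR
90	YBR275C	RIF1	22	[18]	NA	NA	DNA CM
91	YOR368W	RAD17	ND	NA	1	NA	DNA RRR
95	YNL339C	YRF1-6	10	[15]	(1)	NA	DNA RRR
96	YOL090W	MSH2	20	NA	1	[36]	DNA RRR
99	YOR114W	NA	24	NA	1	NA	Unknown
101	YHL013C	OTU2	ND	[17]	NA	[35,37]	Unknown
103	YOR195W	SLK19	27	NA	1	NA	SPB
104	YGR140W	CBF2	34	NA	1 (1)	NA	Cell cycle
106	YNL309W	STB1	15	NA	1 (1)	NA	Cell cycle
107	YOL034W	SMC5	ND	NA	1	NA	DNA RRR
108	YER016W	BIM1	29	NA	2	NA	Cytoskeleton
109	YDR356W	SPC110	33	NA	1	NA	Cytoskeleton
110	YDL105W	NSE4	16	NA	NA	NA	DNA RRR
111	YNL088W	TOP2	34	NA	2	NA	DNA CM
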
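ranking	systematic_name	standard_name	cc_peak	tf_binding	motifs	previous_classifications	functional_class
1	YER001W	MNN1	29	[16-18]	1 (1)	[22,23,36-38]	CW Gly
2	YNL300W	TOS6	30	[15-18]	4	[22,23,35-38]	Unknown
3	YKR013W	PRY2	25	[16-18]	4	[22,23,35,36,38]	Unknown
4	YOL007C	CSI2	24	[15]	4	[22,36]	CW Gly
5	YPL163C	SVS1	28	[15-18]	3 (1)	[22,23,35-38]	Others
6	YPL256C	CLN2	23	[15]	2 (2)	[23,35,36]	DNA RRR/BP
7	YDR297W	SUR2	30	[15]	1	[23]	Others
8	YMR307W	GAS1	36	[15-18]	2 (1)	[22,23,36-38]	CW Gly
9	YDR507C	GIN4	21	[15-18]	1	[23,37,38]	BP
10	YLR183C	TOS4	23	[15]	2 (1)	[22,36]	Others
16	YOL019W	NA	22	[15,17]	1	[36-38]	Unknown
17	YGR140W	CBF2	34	[15]	1 (2)	NA	Cell cycle
18	YNL031C	HHT2	37	[15]	2	[36]	DNA CM
32	YJL173C	RFA3	31	NA	1 (1)	NA	DNA RRR
39	YMR144W	NA	33	[16-18]	1	[35-38]	Unknown
49	YMR179W	SPT21	14	[15-18]	1	[35-38]	Others
51	YPL267W	ACM1	16	[17,18]	1	[35-38]	Unknown
54	YLR121C	YPS3	17	[15]	2	[36]	Others
57	YNL278W	CAF120	ND	[15]	2	NA	Others
61	YHR154W	RTT107	24	NA	1	[36]	DNA RRR
63	YMR304C-A	NA	ND	[16-18]	0	NA	Unknown
65	YHR173C	NA	36	NA	1	NA	Unknown
67	YBL009W	ALK2	36	NA	2	NA	Others
69	YJL080C	SCP160	33	NA	2	NA	Cell cycle
70	YKR090W	PXL1	27	NA	1	NA	BP
71	YGL093W	SPC105	34	NA	1	NA	Cytoskeleton
72	YKL113C	RAD27	20	NA	1	[36]	DNA RRR
73	YBR088C	POL30	20	NA	1	[36]	DNA RRR
76	YGL225W	VRG4	38	NA	2 (1)	NA	CW Gly
77	YDR113C	PDS1	33	NA	0	NA	Cell cycle
79	YLR383W	SMC6	24	NA	1	NA	DNA RRR
81	YGL012W	ERG4	42	[15]	1	NA	Others
84	YPL032C	SVL3	40	NA	1	NA	BP
85	YHR050W	SMF2	ND	NA	1 (1)	NA	Others
86	YKL049C	CSE4	40	NA	1	NA	Cell cycle
87	YBR252W	DUT1	40	NA	1	NA	Others
88	YOR099W	KTR1	34	NA	1 (1)	NA	CW Gly
89	YLL021W	SPA2	31	NA	0 (1)	NA	BP
91	YNL102W	POL1	20	NA	0 (1)	[36]	DNA RRR
92	YJR144W	MGM101	ND	NA	3 (1)	NA	DNA RRR
93	YLR045C	STU2	42	NA	3 (1)	[36]	SPB
94	YAL007C	ERP2	37	NA	1	NA	Others
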
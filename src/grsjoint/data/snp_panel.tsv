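rsid	locus	gene	effect_allele	other_allele	eaf	published_or	grs2
rs243021	1	BCL11A	A	G	0.68	1.03	N
rs7593730	2	RBMS1,ITGB6	C	T	0.83	1.03	N
rs7578326	3	IRS1	A	G	0.85	0.99	N
rs2943641	3	IRS1	C	T	0.93	1.08	N
rs4607103	5	ADAMTS9	C	T	0.63	0.98	N
rs4402960	6	IGF2BP2	T	G	0.25	1.19	Y
rs7756992	7	CDKAL1	G	A	0.52	1.16	Y
rs10440833	7	CDKAL1	A	T	0.40	1.27	Y
rs3734618	9	KCNK15	A	G	0.45	1.10	Y
rs864745	10	JAZF1	T	C	0.77	0.96	N
rs972283	11	KLF14	G	A	0.72	1.09	N
rs896854	12	TP53INP1	T	C	0.32	1.16	Y
rs13266634	13	SLC30A8	C	T	0.59	1.09	Y
rs17584499	14	PTPRD	T	C	0.10	1.13	N
rs564398	15	CDKN2A,CDKN2B	T	C	0.88	1.06	N
rs10811661	15	CDKN2A,CDKN2B	T	C	0.54	1.20	Y
rs13292136	17	CHCHD9	C	T	0.90	0.99	N
rs12779790	18	CDC123,CAMK1D	G	A	0.17	1.11	Y
rs1111875	19	HHEX,IDE	C	T	0.30	1.22	Y
rs5015480	19	HHEX,IDE	C	T	0.17	1.34	Y
rs2237892	21	KCNQ1	C	T	0.67	1.20	Y
rs5215	22	KCNJ11	T	C	0.40	1.15	Y
rs9300039	23	Intergenic	C	A	0.75	1.07	N
rs1552224	24	CENTD2	A	C	0.92	1.08	N
rs1387153	25	MTNR1B	T	C	0.42	0.99	N
rs4760790	26	TSPAN8,LGR5	A	G	0.24	0.99	N
rs7961581	26	TSPAN8,LGR5	C	T	0.21	0.99	N
rs1215468	28	SPRY2	A	G	0.72	1.27	Y
rs7172432	29	C2CD4A,C2CD4B	G	A	0.39	0.96	N
rs11634397	30	ZFAND6	G	A	0.09	0.92	N
rs8050136	31	FTO	A	C	0.12	1.08	N
rs11642841	31	FTO	A	C	0.04	1.00	N
rs12599890	33	CMIP	T	C	0.72	0.94	N
rs391300	34	SRR	C	T	0.71	0.99	N
rs4430796	35	HNF1B,TCF2	G	A	0.30	1.18	Y
rs6017317	36	FITM2-R3HDML-HNF4A	G	T	0.43	1.08	N
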
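gene	rsids	chromosome	positions	minor_allele	major_allele	risk_genotype	d	ci_low	ci_high	source
APOE	rs7412,rs429358	19	44908822,44908684	e4	e3	e4+	0.472	0.14	0.80	ad_risk
CR1	rs3818361	1	207611623	A	G	G/G	0.109	-0.24	0.46	ad_risk
BIN1	rs744373	2	127137039	G	A	A/A	0.003	-0.32	0.33	ad_risk
INPP5D	rs35349669	2	233159830	T	C	T+	0.153	-0.20	0.50	ad_risk
KIBRA	rs17070145	5	168418786	C	T	C/C	0.097	-0.22	0.42	cognition
MEF2C	rs190982	5	88927603	G	A	A/A	0.278	-0.07	0.62	ad_risk
HLA cluster	rs9271192	6	32610753	C	A	C+	0.256	-0.07	0.58	ad_risk
CD2AP	rs9349407	6	47485642	C	G	C+	0.114	-0.21	0.43	ad_risk
NME8	rs2718058	7	37801932	G	A	G+	0.041	-0.28	0.36	ad_risk
ZCWPW1	rs1476679	7	100406823	C	T	T/T	0.149	-0.17	0.47	ad_risk
EPHA1	rs11767557	7	143412046	C	T	T/T	0.061	-0.27	0.39	ad_risk
CSMD1	rs2740931	8	4022021	A	T	A/A	0.201	-0.16	0.56	cognition
CLU	rs11136000	8	27607002	T	C	T+	0.078	-0.25	0.40	ad_risk
PTK2B	rs28834970	8	27337604	C	T	C+	0.030	-0.30	0.36	ad_risk
SPON1	rs11023139	11	14202800	A	G	A+	0.045	-0.44	0.53	cognition
BDNF	rs6265	11	27658369	Met	Val	Met+	0.143	-0.20	0.49	cognition
CELF1	rs10838725	11	47536319	C	T	C+	0.103	-0.22	0.42	ad_risk
MS4A6A	rs610932	11	60171834	T	G	T+	0.167	-0.18	0.52	ad_risk
PICALM	rs3851179	11	86157598	T	C	C/C	0.098	-0.23	0.42	ad_risk
SORL1	rs11218343	11	121564878	C	T	T/T	0.214	-0.68	1.10	ad_risk
KL	rs9536314	13	33054001	VS	WT	VS+	0.160	-0.20	0.52	cognition
FERMT2	rs17125944	14	52933911	C	T	C+	0.277	-0.15	0.71	ad_risk
SLC24A4	rs10498633	14	92460608	T	G	T+	0.110	-0.21	0.43	ad_risk
ABCA7	rs3764650	19	1046521	G	T	G+	0.062	-0.34	0.47	ad_risk
CD33	rs3865444	19	51224706	A	C	A+	0.082	-0.24	0.40	ad_risk
CASS4	rs7274581	20	56443204	C	T	T/T	0.080	-0.36	0.52	ad_risk
COMT	rs4680	22	19963748	Met	Val	Met+	0.098	-0.26	0.45	cognition
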
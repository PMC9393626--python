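gene	entrez	log2fc	pvalue	herb
EREG	2069	0.626	8.91E-06	Gusuibu
PTK2B	2185	1.386	2.03E-04	Gusuibu
VCAN	1462	0.849	2.91E-04	Gusuibu
CAV2	858	1.214	4.29E-04	Gusuibu
PLCG1	5335	1.448	1.14E-03	Gusuibu
PIM1	5292	1.435	1.80E-03	Gusuibu
STAT3	6774	-0.792	3.42E-03	Gusuibu
TXNIP	10628	1.017	8.30E-03	Gusuibu
GADD45A	1647	-0.851	1.25E-02	Gusuibu
CYP26C1	340665	1.296	1.27E-02	Gusuibu
KDR	3791	1.400	1.32E-02	Gusuibu
GNAI1	2770	0.655	1.62E-02	Gusuibu
ARNT	405	-1.500	1.88E-02	Gusuibu
MARC1	64757	1.342	2.03E-02	Gusuibu
GNGT2	2793	1.110	2.70E-02	Gusuibu
POMC	5443	1.586	3.24E-02	Gusuibu
BMF	90427	1.028	3.42E-02	Gusuibu
KAT2B	8850	1.048	3.43E-02	Gusuibu
F5	2153	0.969	3.53E-02	Gusuibu
SHC2	25759	1.798	4.17E-02	Gusuibu
THRB	7068	0.909	4.24E-02	Gusuibu
PIK3R1	5295	0.778	4.81E-02	Gusuibu
HMOX1	3162	1.873	2.87E-36	Roucongrong
EREG	2069	0.795	4.12E-08	Roucongrong
VCAN	1462	-0.990	2.03E-04	Roucongrong
TNFRSF1A	7132	2.819	3.81E-04	Roucongrong
EGFR	1956	-0.593	7.01E-04	Roucongrong
CYP4V2	285440	-1.145	1.02E-03	Roucongrong
SOD2	6648	-1.052	1.05E-03	Roucongrong
MED1	5469	-0.609	1.68E-03	Roucongrong
SUMO2	6613	0.713	3.71E-03	Roucongrong
HRAS	3265	2.482	5.12E-03	Roucongrong
THEM4	117145	-0.715	1.49E-02	Roucongrong
PPP2CA	5515	0.691	1.77E-02	Roucongrong
FOXO4	4303	1.087	1.88E-02	Roucongrong
CYBA	1535	-0.977	1.90E-02	Roucongrong
GNG3	2785	4.330	2.25E-02	Roucongrong
TYK2	7297	-0.663	2.41E-02	Roucongrong
ESR2	2100	-2.243	2.45E-02	Roucongrong
MMP7	4316	1.977	2.68E-02	Roucongrong
BCL2L1	598	-0.797	2.69E-02	Roucongrong
IL1R1	3554	2.682	2.78E-02	Roucongrong
EGF	1950	1.629	3.13E-02	Roucongrong
HSPA8	3312	0.736	3.14E-02	Roucongrong
NR2C2	7182	2.133	3.32E-02	Roucongrong
SIRT3	23410	1.250	3.41E-02	Roucongrong
PIAS1	8554	-0.986	4.27E-02	Roucongrong
BCL6	604	1.112	4.30E-02	Roucongrong
IL6	3569	1.382	1.01E-55	Yinyanghuo
IL8	3576	2.331	5.35E-27	Yinyanghuo
TXN	7295	0.615	1.92E-24	Yinyanghuo
FN1	2335	-1.420	1.06E-14	Yinyanghuo
HSP90B1	7184	-0.640	7.51E-12	Yinyanghuo
HMOX1	3162	1.134	4.38E-11	Yinyanghuo
STAT1	6772	-1.208	9.97E-09	Yinyanghuo
CXCL2	2920	1.716	2.47E-08	Yinyanghuo
CAV1	857	-0.899	5.29E-08	Yinyanghuo
CDKN2A	1029	-0.705	8.18E-08	Yinyanghuo
SDC2	6383	-0.660	3.56E-07	Yinyanghuo
VCAN	1462	-1.675	2.01E-06	Yinyanghuo
EREG	2069	0.942	2.60E-06	Yinyanghuo
CDKN1A	1026	1.609	2.64E-06	Yinyanghuo
ITGAV	3685	-1.131	6.93E-06	Yinyanghuo
IL18	3606	0.619	9.06E-05	Yinyanghuo
LCN2	3934	-0.940	1.70E-04	Yinyanghuo
BAD	572	1.229	2.24E-04	Yinyanghuo
CTNND1	1500	-0.810	3.16E-04	Yinyanghuo
TP53BP2	7159	-0.619	3.40E-04	Yinyanghuo
NCK1	4690	-0.601	4.70E-04	Yinyanghuo
IGFBP7	3490	-1.128	7.29E-04	Yinyanghuo
CXCL1	2919	1.978	7.35E-04	Yinyanghuo
WASF1	8936	-0.623	1.15E-03	Yinyanghuo
RASA1	5921	-4.118	1.41E-03	Yinyanghuo
TP53	7157	-0.781	4.20E-03	Yinyanghuo
NR1H2	7376	0.882	5.24E-03	Yinyanghuo
VCAM1	7412	1.191	5.48E-03	Yinyanghuo
CALM1	801	-0.814	7.22E-03	Yinyanghuo
ARNT	405	1.323	8.66E-03	Yinyanghuo
PPARG	5468	1.447	1.14E-02	Yinyanghuo
NR4A2	4929	1.762	1.34E-02	Yinyanghuo
IL6R	3570	1.563	1.60E-02	Yinyanghuo
SGK1	6446	-0.785	1.87E-02	Yinyanghuo
ATM	472	1.279	1.89E-02	Yinyanghuo
YWHAH	7533	-0.937	2.20E-02	Yinyanghuo
CYP4V2	285440	-1.242	2.32E-02	Yinyanghuo
ROCK1	6093	1.777	2.42E-02	Yinyanghuo
F5	2153	1.260	2.57E-02	Yinyanghuo
IL23A	51561	1.242	2.65E-02	Yinyanghuo
FOXO4	4303	1.443	3.10E-02	Yinyanghuo
CYP2S1	29785	0.841	3.11E-02	Yinyanghuo
ITGB2	3689	1.011	3.28E-02	Yinyanghuo
HDAC1	3065	-0.721	3.32E-02	Yinyanghuo
SOCS5	9655	1.091	3.64E-02	Yinyanghuo
PAK3	5063	-1.565	3.65E-02	Yinyanghuo
LAMC1	3915	-0.622	3.72E-02	Yinyanghuo
FOS	2353	2.111	4.13E-02	Yinyanghuo
PPARGC1A	10891	1.096	4.16E-02	Yinyanghuo
AKT2	208	0.975	4.24E-02	Yinyanghuo
MMP7	4316	1.605	4.53E-02	Yinyanghuo
JUNB	3726	0.822	4.71E-02	Yinyanghuo
PTK2	5747	-0.704	4.77E-02	Yinyanghuo
SFN	2810	1.300	4.94E-02	Yinyanghuo
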
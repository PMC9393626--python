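symbol	entrez	herb
ADRB1	153	Gusuibu
ADRB2	154	Gusuibu
AHR	196	Gusuibu
AKT1	207	Gusuibu
APOB	338	Gusuibu
CAT	847	Gusuibu
CYP1A1	1543	Gusuibu
CYP1B1	1545	Gusuibu
CYP19A1	1588	Gusuibu
ESR1	2099	Gusuibu
NR3C1	2908	Gusuibu
GSTM1	2944	Gusuibu
GSTP1	2950	Gusuibu
IFNG	3458	Gusuibu
IL6	3569	Gusuibu
INSR	3643	Gusuibu
NFE2L2	4780	Gusuibu
NOS3	4846	Gusuibu
PGR	5241	Gusuibu
PLAU	5328	Gusuibu
PON1	5444	Gusuibu
PTGS2	5743	Gusuibu
SREBF1	6720	Gusuibu
TGFB1	7040	Gusuibu
TNF	7124	Gusuibu
ADRB2	154	Roucongrong
AKT1	207	Roucongrong
GSTM1	2944	Roucongrong
IL6	3569	Roucongrong
INSR	3643	Roucongrong
NFE2L2	4780	Roucongrong
NOS3	4846	Roucongrong
PGR	5241	Roucongrong
PLAU	5328	Roucongrong
PON1	5444	Roucongrong
PTGS2	5743	Roucongrong
TGFB1	7040	Roucongrong
TNF	7124	Roucongrong
PARP1	142	Roucongrong
AR	367	Roucongrong
E2F1	1869	Roucongrong
HSF1	3297	Roucongrong
IGF2	3481	Roucongrong
IL10	3586	Roucongrong
PTPN1	5770	Roucongrong
SPP1	6696	Roucongrong
CHEK2	11200	Roucongrong
ADRB2	154	Yinyanghuo
AKT1	207	Yinyanghuo
INSR	3643	Yinyanghuo
NFE2L2	4780	Yinyanghuo
NOS3	4846	Yinyanghuo
PTGS2	5743	Yinyanghuo
TGFB1	7040	Yinyanghuo
PARP1	142	Yinyanghuo
AR	367	Yinyanghuo
IL10	3586	Yinyanghuo
CHEK2	11200	Yinyanghuo
AHR	196	Yinyanghuo
ESR1	2099	Yinyanghuo
GSTP1	2950	Yinyanghuo
IFNG	3458	Yinyanghuo
BIRC5	332	Yinyanghuo
ESR2	2100	Yinyanghuo
HSPB1	3315	Yinyanghuo
IL1A	3552	Yinyanghuo
IL1B	3553	Yinyanghuo
MMP2	4313	Yinyanghuo
PDE3A	5139	Yinyanghuo
CCL2	6347	Yinyanghuo
TP53	7157	Yinyanghuo
VEGFA	7422	Yinyanghuo
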
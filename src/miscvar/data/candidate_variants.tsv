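Gene	Patient	Transcript	Variant	Effect	GenePanel	AF_gnomAD	AF_ABraOM	Inheritance	dbSNP
APOL1	P7, P16, P20	NM_003661.4	c.1164_1169delTTATAA	Frameshift	IEI	1.31%	2.87%	UN	rs71785313
BRCA2	P3	NM_000059.3	c.1138del	Frameshift	IEI	N/A	N/A	AR/AD/UN	rs80359264
C6	P13	NM_000065.3	c.1879del	Frameshift	IEI	0.11%	0.29%	AR	rs61469168
C8A	P24	NM_000562.2	c.1413_1416del	Frameshift	IEI	N/A	N/A	AR	N/A
CD46	P19	NM_002389.4	c.857-2A>C	Splice acceptor	IEI	<0.01%	N/A	AR/AD	rs773618613
CFB	P5, P11	NM_001710.5	c.26T>A	Missense	IEI	3.83%	3.76%	AR/AD/UN	rs4151667
CFB	P12	NM_001710.5	c.94_95delinsTA	Stop gained	IEI	3.83%	N/A	AR/AD/UN	rs4151667
CFHR1	P26	NM_002113.2	c.790+1G>A	Splice donor	IEI	0.25%	0.46%	AR/AD	rs140799744
CFHR3	P21	NM_021023.5	c.796+1G>A	Splice donor	IEI	0.2%	0.09%	AR/AD	rs370108606
CFHR5	P20	NM_030787.3	c.1704T>A	Stop gained	IEI	0.26%	0.34%	AD	rs143140599
CFTR	P12	NM_000492.3	c.1521_1523del	Deletion	IEI	0.72%	0.43%	AR/AD	rs113993960
CFTR	P13	NM_000492.3	c.617T>G	Missense	IEI	0.72%	0.17%	AR/AD	rs113993960
CLPB	P1	NM_001258392.2	c.1132A>G	Missense	IEI	0.02%	N/A	AR/AD	rs144078282
CTC1	P5	NM_025099.5	c.248_251dup	Frameshift	IEI	<0.01%	N/A	AR	rs745467709
DCLRE1C	P24	NM_001033855.2	c.959C>G	Missense	IEI	0.36%	0.77%	AR	rs41298896
ERAP1	P24	NM_016442.3	c.170_173delACGT	Frameshift	Kawasaki	0.03%	N/A	N/A	rs546509120
ERCC6L2	P19	NM_020207.7	c.4095delA	Frameshift	IEI	N/A	N/A	AR	N/A
FANCA	P9	NM_000135.2	c.3349-1G>C	Splice acceptor	IEI	N/A	N/A	AR	rs769862233
FCN3	P6, P16, P18	NM_003665.3	c.349del	Frameshift	IEI	1.62%	3.03%	AR	rs532781899
G6PD	P5, P21, P23, P26, P28	NM_001360016.2	c.202G>A	Missense	Kawasaki	1.16%	4.02%	XL/UN	rs1050828
HAVCR2	P28	NM_032782.4	c.291A>G	Missense	Kawasaki	0.29%	0.34%	AR	rs35960726
HLA-A	P1, P8, P9, P14, P26	NM_002116.7	c.265_266del	Frameshift	Kawasaki	0.33%	N/A	UN	rs1491212130
HLA-A	P1, P8, P9, P14, P26	NM_002116.7	c.268_269insG	Frameshift	Kawasaki	0.01%	N/A	UN	rs576213756
HLA-A	P1, P8, P14, P26	NM_002116.7	c.272_273insC	Frameshift	Kawasaki	0.01%	1.24%	UN	rs775079480
HLA-A	P1, P8, P9, P14, P26	NM_002116.7	c.295_296insTA	Frameshift	Kawasaki	0.01%	N/A	UN	rs774211961
HLA-A	P1, P8, P14, P26	NM_002116.7	c.301_302del	Frameshift	Kawasaki	0.01%	N/A	UN	rs750632693
HLA-A	P8	NM_002116.7	c.626_627dup	Frameshift	Kawasaki	0.26%	N/A	UN	rs199474609
HLA-A	P19, P20	NM_002116.8	c.619G>T	Missense	Kawasaki	0.05%	N/A	UN	rs62687162
HLA-A	P2, P25	NM_002116.7	c.257delA	Frameshift	Kawasaki	0.01%	N/A	UN	rs200082950
HLA-A	P2, P25	NM_002116.7	c.261delG	Frameshift	Kawasaki	0.01%	N/A	UN	rs199474423
HLA-A	P2, P25	NM_002116.7	c.265_266insACAGATCT	Frameshift	Kawasaki	0.01%	N/A	UN	rs752540700
IFIH1	P4	NM_022168.3	c.1641+1G>C	Splice donor	IEI	0.67%	1.28%	AR/AD/UN	rs35337543
IFNA21	P29	NM_002175.2	c.376G>T	Stop gained	MIS-C	0.05%	0.13%	N/A	rs146777169
IRF3	P10	NM_001197122.1	c.1231C>T	Stop gained	IEI/Covid-19	0.03%	N/A	AD	rs149842990
JAK3	P1, P17	NM_000215.3	c.2164G>A	Missense	IEI	0.84%	0.94%	AR	rs3213409
KMT2D	P22	NM_003482.3	c.2533del	Frameshift	IEI	N/A	N/A	AD	rs767415197
MASP2	P4, P17	NM_006610.3	c.359A>G	Missense	IEI	2.18%	2.05%	AR	rs72550870
PMS2	P11, P27	NM_000535.6	c.2186_2187del	Frameshift	IEI	<0.01%	1.33%	AR/AD	rs587779335
POLE	P11	NM_006231.3	c.2864+1G>C	Splice donor	IEI	N/A	N/A	AR/AD	N/A
PRF1	P11, P19	NM_001083116.1	c.272C>T	Missense	IEI	2.92%	4.96%	AR/UN	rs35947132
PRF1	P13, P20	NM_001083116.1	c.11G>A	Missense	IEI	0.84%	1.92%	AR/UN	rs35418374
RAD51	P21	NM_002875.4	c.449G>A	Missense	IEI	0.05%	0.17%	AD	rs121917739
RANBP2	P27	NM_006267.4	c.7309_7311delinsTAA	Missense	IEI	N/A	N/A	AD	N/A
SH3BP2	P26	NM_001145855.1	c.221G>A	Stop gained	IEI	N/A	N/A	AD	N/A
SPINK5	P2	NM_006846.3	c.2468dup	Frameshift	IEI	0.13%	N/A	AR	rs565782662
TERC	P7	NR_001566.1	n.58G>A	Regulatory	IEI	0.52%	1.54%	AD	rs113487931
TERT	P20	NM_198253.2	c.1234C>T	Missense	IEI	0.32%	0.17%	AR/AD/UN	rs34094720
TNFRSF13B	P15, P29	NM_012452.2	c.204dup	Frameshift	IEI	0.04%	N/A	AR/AD/UN	rs72553875
TP53	P21, P22	NM_000546.5	c.467G>A	Frameshift	IEI	<0.01%	N/A	AR/AD/UN	rs371524413
ZFHX3	P20	NM_006885.3	c.10536_10537del	Frameshift	Kawasaki	N/A	N/A	UN	N/A
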
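panel	gene
IEI	APOL1
IEI	BRCA2
IEI	C6
IEI	C8A
IEI	CD46
IEI	CFB
IEI	CFHR1
IEI	CFHR3
IEI	CFHR5
IEI	CFTR
IEI	CLPB
IEI	CTC1
IEI	DCLRE1C
IEI	ERCC6L2
IEI	FANCA
IEI	FCN3
IEI	IFIH1
IEI	IRF3
IEI	JAK3
IEI	KMT2D
IEI	MASP2
IEI	PMS2
IEI	POLE
IEI	PRF1
IEI	RAD51
IEI	RANBP2
IEI	SH3BP2
IEI	SPINK5
IEI	TERC
IEI	TERT
IEI	TNFRSF13B
IEI	TP53
KD	ERAP1
KD	G6PD
KD	HAVCR2
KD	HLA-A
KD	ZFHX3
COVID19	IRF3
MISC	IFNA21
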
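Category	Pathway	StudyGenes	LiteratureGenes	CombinedGenes
study_only	Complement system	C6,C8A,CD46,CFB,CFHR1,CFHR5,FCN3,MASP2	-	C6,C8A,CD46,CFB,CFHR1,CFHR3,CFHR5,FCN3,MASP2
study_only	Hematopoiesis and immune system development	BRCA2,CTC1,DCLRE1C,G6PD,HAVCR2,IFNA21,JAK3,PMS2,TNFRSF13B,TP53	-	AP3B1,BRCA2,CD46,CTC1,DCLRE1C,FANCA,G6PD,GAB2,HAVCR2,IFNA21,IFNA4,IFNA6,IFNB1,JAK3,KMT2D,LY9,PMS2,SIGLEC15,SOCS1,SPINK5,TLR3,TNFRSF13B,TP53
study_only	Type 2 interferon signaling pathway	HLA-A,IRF3,TP53	-	HLA-A,IRF3,STXBP2,TLR3,TP53
shared	Adaptive immune B cell response	C6,C8A,CD46,CFHR1,CFHR3,CFHR5,DCLRE1C,HLA-A,IFNA21,JAK3,MASP2,PRF1,TNFRSF13B,TP53	CD84,DOCK8,IFNA21,IFNA4,IFNA6,IFNB1,LY9,UNC13D	AP3B1,C6,C8A,CD46,CD84,DCLRE1C,DOCK8,ERAP1,HLA-A,IFNA21,IFNA4,IFNA6,IFNB1,JAK3,LY9,MASP2,PRF1,RAB27A,SOCS1,TNFRSF13B,TP53,UNC13D
shared	Adaptive immune T cell response	C6,C8A,CD46,CFHR1,CFHR3,CFHR5,FANCA,HAVCR2,HLA-A,IFNA21,JAK3,MASP2,PRF1,SPINK5,TNFRSF13B	CD84,DOCK8,IFNA21,IFNA4,IFNA6,IFNB1,LY9,LYST,RAB27A,UNC13D	AP3B1,C6,C8A,CD46,CD84,DOCK8,ERAP1,FANCA,HAVCR2,HLA-A,IFNA21,IFNA4,IFNA6,IFNB1,JAK3,LY9,LYST,MASP2,PRF1,RAB27A,SOCS1,SPINK5,TNFRSF13B,TP53,UNC13D
shared	Cytokine-mediated signaling pathways	CD46,CLPB,HAVCR2,HLA-A,IFIH1,IRF3,JAK3	CD84,CYBB,DOCK8,GAB2,IFIH1,IFNA21,IFNA4,IFNA6,IFNAR1,IFNAR2,IFNB1,IL22RA2,IRAK3,IRF3,LY9,NLRP12,NLRP2,SOCS1,STXBP2,TLR3,TLR6,TRAF3	CD46,CD84,CLPB,CYBB,DOCK8,GAB2,HAVCR2,HLA-A,IFIH1,IFNA21,IFNA4,IFNA6,IFNAR1,IFNAR2,IFNB1,IL22RA2,IRAK3,IRF3,JAK3,LY9,NLRP12,NLRP2,SOCS1,STXBP2,TLR3,TLR6,TNFRSF13B,TP53,TRAF3
shared	DNA-related processes	BRCA2,CTC1,DCLRE1C,ERCC6L2,FANCA,IRF3,PMS2,POLE,RAD51,TERT,TP53	IRAK3,NLRP12,NLRP2,TLR3,TLR6,TRAF3	BRCA2,CTC1,DCLRE1C,ERCC6L2,FANCA,HAVCR2,IRAK3,IRF3,NLRP12,NLRP2,PMS2,POLE,RAD51,TERC,TERT,TLR3,TLR6,TP53,TRAF3,XIAP
shared	Response to bacterium	HAVCR2,SPINK5	IFI44,IFNAR1,IRAK3,IRF3,LYST,SNX3,TLR3,TLR6	ERAP1,HAVCR2,HLA-A,IFI44,IFNAR1,IRAK3,IRF3,LYST,SNX3,SPINK5,TLR3,TLR6
shared	Response to virus	CD46,CLPB,FCN3,HAVCR2,HLA-A,IFIH1,IFNA21,IRF3,PRF1,TP53	EXOSC5,IFI44,IFI44L,IFIH1,IFNA4,IFNA6,IFNA21,IFNAR1,IFNAR2,IFNB1,IRAK3,IRF3,LGALS8,LYST,RNASE2,TLR3,TRAF3,UNC13D	CLPB,EXOSC5,FCN3,HAVCR2,HLA-A,IFI44,IFI44L,IFIH1,IFNA21,IFNA4,IFNA6,IFNAR1,IFNAR2,IFNB1,IRAK3,IRF3,LGALS8,LYST,PRF1,RNASE2,STXBP2,TLR3,TP53,TRAF3,UNC13D
shared	Type 1 interferon signaling pathway	HAVCR2,HLA-A,IFIH1,IFNA21,IRF3	IFIH1,IFNA21,IFNA4,IFNA6,IFNAR1,IFNAR2,IFNB1,IRF3,TLR3,TRAF3	HAVCR2,HLA-A,IFIH1,IFNA21,IFNA4,IFNA6,IFNAR1,IFNAR2,IFNB1,IRF3,TLR3,TRAF3
literature_only	Blood coagulation	-	AP3B1,DOCK8,IFNA21,IFNA4,IFNA6,IFNB1,PEAR1,RAB27A	AP3B1,DOCK8,IFNA21,IFNA4,IFNA6,IFNB1,PEAR1,RAB27A
literature_only	Myeloid leukocyte activation	-	CD84,CYBB,GAB2,RAB27A,RNASE2,STXBP2,TLR3,TLR6,UNC13D	AP3B1,C6,C8A,CD46,CD84,CYBB,DCLRE1C,DOCK8,FANCA,GAB2,HAVCR2,HLA-A,IFNA21,IFNA4,IFNA6,IFNB1,JAK3,LY9,LYST,MASP2,PRF1,RAB27A,RNASE2,SIGLEC15,SOCS1,SPINK5,STXBP2,TLR3,TLR6,TNFRSF13B,TP53,UNC13D
literature_only	NK cell activation	-	IFNA21,IFNA4,IFNA6,IFNB1,LYST,RAB27A,UNC13D	IFNA21,IFNA4,IFNA6,IFNB1,LYST,RAB27A,UNC13D
literature_only	Regulation of inflammatory pathways	-	AP3B1,CD163,CD84,CYBB,IFIH1,IFNA21,IFNA4,IFNA6,IFNAR1,IFNAR2,IFNB1,IL22RA2,IRAK3,IRF3,NLRP12,NLRP2,SOCS1,TLR3,TLR6,TRAF3,UNC13D,XIAP	AP3B1,CD163,CD84,CYBB,FANCA,HAVCR2,IFIH1,IFNA21,IFNA4,IFNA6,IFNAR1,IFNAR2,IFNB1,IL22RA2,IRAK3,IRF3,JAK3,NLRP12,NLRP2,SOCS1,TLR3,TLR6,TRAF3,UNC13D,XIAP
literature_only	Secretion and vesicle dependent transport	-	AP3B1,CD163,CD84,CYBB,GAB2,GOLGA4,IRF3,LYST,NLRP12,PEAR1,PLIN3,RAB27A,RNASE2,SNX3,SOCS1,STXBP2,UNC13D	CD84,CFTR,GAB2,IRF3,NLRP12,RAB27A,SOCS1,STXBP2,UNC13D
literature_only	Type 3 interferon signaling pathway	-	IFIH1,TLR3	IFIH1,TLR3
combined_only	Angiogenesis	-	-	C6,CYBB,ERAP1,TERC,TERT,TLR3
combined_only	Cell adhesion	-	-	AP3B1,CD46,DOCK8,HAVCR2,HLA-A,IFNB1,JAK3,SOCS1,SPINK5,UNC13D,ZFHX3
combined_only	Exocytosis	-	-	CD84,CFTR,GAB2,RAB27A,STXBP2,UNC13D
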
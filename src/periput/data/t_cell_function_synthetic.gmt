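t_cytotoxicity	synthetic placeholder members	GZMA	GZMB	GZMH	GZMK	PRF1	GNLY	NKG7	KLRK1
t_inflammation_promotion	synthetic placeholder members	IL1B	IL6	CXCL8	CCL3	IL18	PTGS2	NLRP3	S100A9
t_chemokine_cytokine	synthetic placeholder members	CCL5	CCL4	XCL1	XCL2	IFNG	IL2	TNF	FLT3LG
t_chemokine_cytokine_receptor	synthetic placeholder members	CCR5	CXCR3	CXCR4	CCR7	IL2RB	IL7R	IL15RA	IL12RB2
t_parainflammation	synthetic placeholder members	ICAM1	PLAUR	ANXA1	TIMP1	CD55	LGALS3	SERPINB1	S100A8
t_co_stimulation	synthetic placeholder members	CD28	ICOS	TNFRSF9	TNFRSF4	TNFRSF18	CD27	CD40LG	SLAMF1
t_co_inhibition	synthetic placeholder members	CTLA4	BTLA	CD160	LAIR1	VSIR	TIGIT	CD274	PDCD1LG2
t_exhaustion	synthetic placeholder members	PDCD1	HAVCR2	LAG3	TOX	ENTPD1	BATF	EOMES	CD38
t_impaired_persistence	synthetic placeholder members	BAX	FAS	CASP3	CASP8	BID	TP53	CDKN1A	ANXA5
t_tissue_residency	synthetic placeholder members	CD69	ITGAE	ITGA1	ZNF683	RGS1	CRTAM	RBPJ	DUSP6
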
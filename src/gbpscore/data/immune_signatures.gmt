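APM	antigen processing and presenting machinery (MHC class I pathway)	HLA-A	HLA-B	HLA-C	B2M	TAP1	TAP2	TAPBP	NLRC5	PSMB8	PSMB9
CYT	cytolytic activity score genes	GZMA	PRF1
IFNG6	6-gene interferon-gamma response signature	IFNG	STAT1	IDO1	CXCL10	CXCL9	HLA-DRA
GEP	18-gene T-cell-inflamed gene expression profile	CCL5	CD27	CD274	CD276	CD8A	CMKLR1	CXCL9	CXCR6	HLA-DQA1	HLA-DRB1	HLA-E	IDO1	LAG3	NKG7	PDCD1LG2	PSMB10	STAT1	TIGIT
CIC_STEP1_ANTIGEN_RELEASE	cancer-immunity cycle step 1: release of cancer cell antigens	HMGB1	CALR	ANXA1	HSP90AA1
CIC_STEP2_ANTIGEN_PRESENTATION	cancer-immunity cycle step 2: cancer antigen presentation	TAP1	TAP2	B2M	HLA-DRA	CD80	CD86	CD40	BATF3
CIC_STEP3_PRIMING_ACTIVATION	cancer-immunity cycle step 3: priming and activation	CD28	ICOS	IL2	IL12A	CD27	TNFRSF9
CIC_STEP4_TRAFFICKING	cancer-immunity cycle step 4: T-cell trafficking	CXCL9	CXCL10	CXCL11	CCL5	CX3CL1
CIC_STEP5_INFILTRATION	cancer-immunity cycle step 5: T-cell infiltration into tumor	ICAM1	VCAM1	SELE	ITGB2	ITGAL
CIC_STEP6_RECOGNITION	cancer-immunity cycle step 6: recognition of cancer cells	CD8A	CD3D	CD3E	TRAC	KLRD1
CIC_STEP7_KILLING	cancer-immunity cycle step 7: killing of cancer cells	GZMA	GZMB	PRF1	IFNG	FASLG	TNF
CD8_T_CELLS	CD8+ T-cell infiltration signature	CD8A	CD8B	GZMK	CD3D	CD3E	CD3G
NK_CELLS	natural killer cell signature	KLRD1	KLRF1	NCR1	NKG7	GNLY
MACROPHAGES	macrophage signature	CD68	CD163	MSR1	MRC1	CSF1R
TREGS	regulatory T-cell signature	FOXP3	IL2RA	IKZF2	CTLA4
B_CELLS	B-cell signature	CD19	MS4A1	CD79A	CD79B	BLK
DENDRITIC_CELLS	dendritic cell signature	CD1C	BATF3	CLEC9A	FLT3	ITGAX
TH1_CELLS	Th1 cell signature	TBX21	IFNG	IL12RB2	STAT4	CXCR3
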
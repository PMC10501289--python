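ESTIMATE_IMMUNE	synthetic stand-in: curated representative immune-infiltrate genes (not the published 141-gene ESTIMATE list; replace with the published GMT for calibrated purity)	PTPRC	CD2	CD3D	CD3E	CD48	CD52	CD53	LAPTM5	CCL5	CXCL9	GZMA	GZMB	PRF1	IL7R	KLRB1	CD8A	LCK	ZAP70	CD27	SASH3
ESTIMATE_STROMAL	synthetic stand-in: curated representative stromal genes (not the published 141-gene ESTIMATE list; replace with the published GMT for calibrated purity)	COL1A1	COL1A2	COL3A1	COL5A1	COL6A3	DCN	FAP	FBLN1	LUM	POSTN	THBS2	VCAN	SPARC	ACTA2	PDGFRB	FN1	MMP2	TAGLN	CDH11	FBN1
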
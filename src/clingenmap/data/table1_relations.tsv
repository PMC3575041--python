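clinical_item	genes
Abdominal pain	FOS;HFE;NRAS;TP53
Blood glucose	BAX;CCND1;CTNNB1;FGFR3;FOS;PPARG;SRG;TLR2;TP53
Carcinoembryonic antigen	APC;BAX;CCND1;CEACAM5;CEACAM7;CEACAM1;CTNNB1;DCC;EGFR;ERBB2;MLH1;MSH2;PSG2;SRC;TLR2;TP53
CA19-9 antigen	CTNNB1;NRAS;TP53;SRC
Colorectal neoplasms staging	APC;CCND1;CTNNB1;MTHFR;PPARG;TP53
Crohn's disease	APC;BAX;CCND1;CTNNB1;DCC;MTHFR;NRAS;PPARG;TLR2;TP53
Diabetes mellitus	APC;BAX;CCND1;CHEK2;CTNNB1;DCC;FGFR3;MTHFR;NRAS;PPARG;PTPN12;SRC;TLR2;TP53
Dyspepsia	PPARG
Intestinal obstruction	APC;CCND1;MSH2;PPARG;TLR2
Lymphatic metastases	MCC;TP53;APC;BAX;CCND1;CTNNB1
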
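# Re-evaluation of C-terminal CaaX motifs in lamins of species previously
# reported to lack one (plus the two crustacean re-annotations).
# nls/ltd: feature annotations as published (fixture annotation, not recomputed).
clade	species	cterm	nls	ltd
Choanoflagellata	Salpingoeca rosetta lamin-1	ESSTWAIMRD	yes	yes
Choanoflagellata	Salpingoeca rosetta lamin-2	CSLM	yes	yes
Porifera	Amphimedon queenslandica	CIIS	yes	yes
Arthropoda	Eurytemora affinis	CVIM	yes	yes
Arthropoda	Lepeophtheirus salmonis	CSVM	yes	yes
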
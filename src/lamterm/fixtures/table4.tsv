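# Amino acid composition (%) of the 10 C-terminal residues of alternative
# lamin C-termini of Annelida, plus the plant NMCP1 consensus.
# aliph = I,L,V; arom = F,W,Y; pos = K,R,H; neg = D,E; tiny = G,A,S.
# Rows are transcribed exactly as printed; the Amphisamytha carldarei row is
# internally inconsistent (printed peptide computes to pos 20 / tiny 30).
clade	species	cterm	aliph	arom	pos	neg	tiny
Clitellata	Helobdella robusta-1	SSKGWLSFLG	20	20	10	0	50
Clitellata	Helobdella robusta-2	ASSLITGFFL	30	20	0	0	40
Clitellata	Hirudo medicinalis-1	GWLSFLSIMG	30	20	0	0	40
Clitellata	Hirudo medicinalis-2	ASSLITGMFL	30	10	0	0	40
Clitellata	Hirudo verbana-1	GWLSFLSIMG	30	20	0	0	40
Clitellata	Hirudo verbana-2	ASSLITGMFL	30	10	0	0	40
Clitellata	Amynthas corticis-1	TWSLFSIVLK	40	20	10	0	20
Clitellata	Amynthas corticis-2	RLSSIFNILM	40	10	10	0	20
Clitellata	Amynthas gracilis	SWSLFSIVLK	40	20	10	0	30
Clitellata	Eisenia fetida-1	TWSLFSVLLK	40	20	10	0	20
Clitellata	Eisenia fetida-2	RLSSIFNILM	40	10	10	0	20
Clitellata	Eisenia fetida-3	WRWSLFSFLK	20	40	20	0	20
Clitellata	Glossoscolex paulistus-1	WGWPLFGFMK	10	40	10	0	20
Clitellata	Glossoscolex paulistus-2	SWSLFSVLLK	40	20	10	0	30
Clitellata	Lumbricus castaneus-1	WRWSLFSFLK	20	40	20	0	20
Clitellata	Lumbricus castaneus-2	RLSSIFNILM	40	10	10	0	20
Clitellata	Lumbricus rubellus-1	TWSLFSVLLK	40	20	10	0	20
Clitellata	Lumbricus rubellus-2	RLSSIFNILM	40	10	10	0	20
Clitellata	Lumbricus rubellus-3	WRWSLFSFLK	20	40	20	0	20
Terebelliformia	Pectinaria gouldii	NGQRTWFWWN	0	40	10	0	10
Terebelliformia	Anobothrus sp.	SRHSWFWWTK	0	40	30	0	20
Terebelliformia	Amphisamytha carldarei	GSRSWFWWNK	0	40	30	0	20
Terebelliformia	Amphicteis gunneri	GRRSWFWWNK	0	40	30	0	20
Terebelliformia	Hypania invalida	KRRSWFFWSK	0	40	40	0	20
Terebelliformia	Alvinella caudata	EGRRKWFWWN	0	40	30	10	10
Terebelliformia	Alvinella pompejana	EGRRKWFWWN	0	40	30	10	10
Terebelliformia	Paralvinella fijiensis	GRRSWFWWNK	0	40	30	0	20
Terebelliformia	Paralvinella palmiformis	GRRSWFWWNK	0	40	30	0	20
Terebelliformia	Paralvinella grasslei	SRRSWFWWNK	0	40	30	0	20
Terebelliformia	Melinna oculata	GRRSWFFWSK	0	40	30	0	30
Terebelliformia	Eupolymnia crassicornis	GRRSWFWWNK	0	40	30	0	20
Terebelliformia	Polycirrus carolinensis	SESRSWFWWK	0	40	20	10	30
Terebelliformia	Neoamphitrite robusta	ARRSWFWWNK	0	40	30	0	20
Terebelliformia	Thelepus sp.	SRRSWFWWNK	0	40	30	0	20
Terebelliformia	Trichobranchus roseus	SSRRSWFWWN	0	40	20	0	30
Terebelliformia	Terebellides sp	SGRGWFFWRN	0	40	20	0	30
Arenicolidae	Arenicola marina	NGRSSWLWWR	10	30	20	0	30
Arenicolidae	Abarenicola pacifica	ENGRSWLWWR	10	30	20	10	20
Opheliidae	Thoracophelia mucronata	WFPSLFSILK	30	30	10	0	20
Capitellidae	Capitella teleta	WSWSFFSMLR	10	40	10	0	30
Echiura	Urechis unicinctus	WGWSFFSVMK	10	40	10	0	30
Plantae	Plant NMCP1 consensus	GKKLWNFLTT	20	20	20	0	10
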
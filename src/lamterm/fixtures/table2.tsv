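# Amino acid composition (%) of the 10 C-terminal residues of Rotifera lamins.
# aliph = I,L,V; arom = F,W,Y; pos = K,R,H; neg = D,E; tiny = G,A,S.
# The **C** marks the bold-printed cysteine of the non-prenylatable CSEE terminus.
# Percentages are transcribed exactly as printed, including the internally
# inconsistent Brachionus rotundiformis row (denominator 9 instead of 10).
clade	species	cterm	aliph	arom	pos	neg	tiny
Monogonata	Brachionus koreanus	KFLGLWKSQP	20	20	20	0	20
Monogonata	Brachionus angularis	VNKFFNLWKN	20	30	20	0	0
Monogonata	Brachionus calyciflorus	VDKDANVSFI	30	10	10	20	20
Monogonata	Brachionus manjavacas	AVQKFLGLWK	30	20	20	0	20
Monogonata	Brachionus paranguensis	AVQKFLGLWK	30	20	20	0	20
Monogonata	Brachionus plicatilis	AVQKFLGLWK	30	20	20	0	20
Monogonata	Brachionus rotundiformis	QKFLGLWKTG	22	22	22	0	22
Monogonata	Proales similis	SSRKFFAFWK	0	40	30	0	30
Acanthocephala	Macracanthorhynchus hirudinaceus	VVDIDFLRIL	60	10	10	20	0
Acanthocephala	Pomphorhynchus laevis-1	SRLFNLFQNN	20	20	10	0	10
Acanthocephala	Pomphorhynchus laevis-2	PMDPSEKNSI	10	0	10	20	20
Seisonidea	Seison nebaliae-1a	VQYSMN**C**SEE	10	10	0	20	20
Seisonidea	Seison nebaliae-1b	QKLVRSRKLN	30	0	40	0	10
Seisonidea	Seison nebaliae-2	YAMEYNTVVE	20	20	0	20	10
Bdelloidea	Adineta ricciae	VVAEKVVSVK	50	0	20	10	20
Bdelloidea	Adineta vaga-1a/b	VVAEKIVTLK	50	0	20	10	10
Bdelloidea	Adineta vaga-2a/b	VVAEKIVTVK	50	0	20	10	10
Bdelloidea	Didymodactylos carnosus-1	DDDCKVDKSI	20	0	20	40	10
Bdelloidea	Didymodactylos carnosus-2	IVAEKILTIK	50	0	20	10	10
Bdelloidea	Rotaria magnacalcarata	VIVEKTVTVK	50	0	20	10	0
Bdelloidea	Rotaria rotatoria	VIAEKTVTVK	40	0	20	10	10
Bdelloidea	Rotaria socialis	VIAEKTVTVK	40	0	20	10	10
Bdelloidea	Rotaria sordida	IVAEKTITIK	40	0	20	10	10
Bdelloidea	Rotaria tardigrada	VVAEKTITIK	40	0	20	10	10
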
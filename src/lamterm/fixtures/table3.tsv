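# Amino acid composition (%) of the 10 C-terminal residues of Cephalopoda lamins.
# aliph = I,L,V; arom = F,W,Y; pos = K,R,H; neg = D,E; tiny = G,A,S.
clade	species	cterm	aliph	arom	pos	neg	tiny
Cephalopoda	Octopus kaurna	TPQKKTWAFW	0	30	20	0	10
Cephalopoda	Octopus minor	TPQKKTWAFW	0	30	20	0	10
Cephalopoda	Octopus vulgaris/sinensis	TPQKKGWIFW	10	30	20	0	10
Cephalopoda	Octopus maya	TPQKKGWIFW	10	30	20	0	10
Cephalopoda	Enteroctopus megalocyathus	PSQKKSWIFW	10	30	20	0	20
Cephalopoda	Hapalochlaena maculosa	PSQKKSWLFW	10	30	20	0	20
Cephalopoda	Vampyroteuthis infernalis	SQQKKGWLFW	10	30	20	0	20
Cephalopoda	Idiosepius notoides	SQQKKGWLFW	10	30	20	0	20
Cephalopoda	Onychoteuthis banksii	SQQKKGWIFW	10	30	20	0	20
Cephalopoda	Sthenoteuthis oualaniensis	SQQKKGWLFW	10	30	20	0	20
Cephalopoda	Octopoteuthis deletron	SQQKKGWLFW	10	30	20	0	20
Cephalopoda	Pterygioteuthis hoylei	SQQKKSWLFW	10	30	20	0	20
Cephalopoda	Chiroteuthis calyx	SQQKKGWLFW	10	30	20	0	20
Cephalopoda	Watasenia scintillans	SQQKKGWLFW	10	30	20	0	20
Cephalopoda	Dosidicus gigas	SQQKKGWLFW	10	30	20	0	20
Cephalopoda	Architeuthis dux	SQQKKGWLFW	10	30	20	0	20
Cephalopoda	Euprymna tasmanica	SQQKKGWLFW	10	30	20	0	20
Cephalopoda	Euprymna scolopes	SQQKKGWLFW	10	30	20	0	20
Cephalopoda	Sepiella maindroni	AQQRKGWLFW	10	30	20	0	20
Cephalopoda	Sepia pharaonis	AQQRKGWLFW	10	30	20	0	20
Cephalopoda	Sepia esculenta	AQQRKGWLFW	10	30	20	0	20
Cephalopoda	Sepioloidea lineolata	QQKKGGWLFW	10	30	20	0	20
Cephalopoda	Nautilus pompilius	TGQRRSWLFW	10	30	20	0	20
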
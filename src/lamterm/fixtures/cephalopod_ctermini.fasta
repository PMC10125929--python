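>Octopus_kaurna
TPQKKTWAFW
>Octopus_minor
TPQKKTWAFW
>Octopus_vulgaris_sinensis
TPQKKGWIFW
>Octopus_maya
TPQKKGWIFW
>Enteroctopus_megalocyathus
PSQKKSWIFW
>Hapalochlaena_maculosa
PSQKKSWLFW
>Vampyroteuthis_infernalis
SQQKKGWLFW
>Idiosepius_notoides
SQQKKGWLFW
>Onychoteuthis_banksii
SQQKKGWIFW
>Sthenoteuthis_oualaniensis
SQQKKGWLFW
>Octopoteuthis_deletron
SQQKKGWLFW
>Pterygioteuthis_hoylei
SQQKKSWLFW
>Chiroteuthis_calyx
SQQKKGWLFW
>Watasenia_scintillans
SQQKKGWLFW
>Dosidicus_gigas
SQQKKGWLFW
>Architeuthis_dux
SQQKKGWLFW
>Euprymna_tasmanica
SQQKKGWLFW
>Euprymna_scolopes
SQQKKGWLFW
>Sepiella_maindroni
AQQRKGWLFW
>Sepia_pharaonis
AQQRKGWLFW
>Sepia_esculenta
AQQRKGWLFW
>Sepioloidea_lineolata
QQKKGGWLFW
>Nautilus_pompilius
TGQRRSWLFW
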
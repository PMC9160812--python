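gene	locations
KRT18	Cytoplasm;Intermediate filaments
KRT8	Cytoplasm;Intermediate filaments
NAPSA	Cytoplasm;Vesicles
MUC1	Plasma membrane;Secreted
WFDC2	Cytoplasm
SFTPB	Cytoplasm;Vesicles
HOPX	Nucleoplasm
KRT7	Cytoplasm;Intermediate filaments
EPCAM	Plasma membrane
KRT19	Cytoplasm;Intermediate filaments
SFTA2	Cytoplasm
ZFP36L1	Nucleoplasm;Cytoplasm
ERRFI1	Cytoplasm
C8orf4	Cytoplasm
ELF3	Nucleoplasm
NKX2-1	Secreted;Nucleoplasm
RNASE1	Cytoplasm
GPRC5A	Plasma membrane
CLDN4	Plasma membrane;Cell junctions
SLC34A2	Plasma membrane
IRX2	Nucleoplasm
CAPN8	Cytoplasm
SPINK13	Secreted
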
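# name	recognition (IUPAC)	top-strand cut offset from pattern start
PstI	CTGCAG	5
BamHI	GGATCC	1
EcoRI	GAATTC	1
EcoRV	GATATC	3
NdeI	CATATG	2
XbaI	TCTAGA	1
BccI	CCATC	9
FokI	GGATG	14
XmnI	GAANNNNTTC	5
DraI	TTTAAA	3
TaqI	TCGA	1
MseI	TTAA	1
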
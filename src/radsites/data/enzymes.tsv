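# name	recognition	cut_offset
AgeI	ACCGGT	1
ApeKI	GCWGC	1
BamHI	GGATCC	1
ClaI	ATCGAT	2
EcoRI	GAATTC	1
FseI	GGCCGGCC	6
KpnI	GGTACC	5
MluI	ACGCGT	1
NcoI	CCATGG	1
NotI	GCGGCCGC	2
NsiI	ATGCAT	5
PacI	TTAATTAA	5
PmeI	GTTTAAAC	4
PstI	CTGCAG	5
SbfI	CCTGCAGG	6
SgrAI	CRCCGGYG	2
SphI	GCATGC	5
XhoI	CTCGAG	1
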
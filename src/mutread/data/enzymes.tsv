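name	recognition	cut_offset
PstI	CTGCAG	5
ApoI	RAATTY	1
EcoRI	GAATTC	1
BamHI	GGATCC	1
MfeI	CAATTG	1
NcoI	CCATGG	1
NsiI	ATGCAT	5
SphI	GCATGC	5
SspI	AATATT	3
DraI	TTTAAA	3
MluCI	AATT	0
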
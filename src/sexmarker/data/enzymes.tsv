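name	recognition	cut_offset
EcoRI	GAATTC	1
BamHI	GGATCC	1
HindIII	AAGCTT	1
EcoRV	GATATC	3
PstI	CTGCAG	5
SalI	GTCGAC	1
XbaI	TCTAGA	1
XhoI	CTCGAG	1
KpnI	GGTACC	5
SacI	GAGCTC	5
SpeI	ACTAGT	1
NdeI	CATATG	2
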
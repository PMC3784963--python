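accession	locus_tag	name
P0A3H5	SCO2950	HupA
P0A3H7	SCO5556	HupS
Q9KXR9	SCO1480	sIHF
Q9X8N1	SCO3375	Lsr2
O52732	SCO1489	BldD
Q9XA42	SCO3571	CRP
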
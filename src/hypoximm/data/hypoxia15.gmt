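HYPOXIA15	HIF1A-associated hypoxia signature	ACOT7	ADM	ALDOA	CDKN3	ENO1	LDHA	MIF	MRPS17	NDRG1	P4HA1	PGAM1	SLC2A1	TPI1	TUBB6	VEGFA
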
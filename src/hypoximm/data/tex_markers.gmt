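TEX	exhausted T cell markers	PDCD1	LAG3	HAVCR2	CD8A	CD8B	CD3E	ENTPD1	TGAE	ITGAE	BATF	NR4A1
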
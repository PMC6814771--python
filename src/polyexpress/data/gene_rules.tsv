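gene	terminal_exon_rule	n_exons
LDLR	1	18
APOB	1	29
PCSK9	1	12
MC4R	0	1
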
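ligand	receptor
vegfc	kdr
edn1	ednrb
bdnf	ntrk1
cxcl12	cxcr4
kitl	kit
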
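sequence	clash_dna	clash_protein	interaction_energy	sidechain_hbond
CGTGGGAA	11.16	37.67	-12.94	-16.75
TGTGGGAA	11.36	37.74	-10.93	-14.76
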
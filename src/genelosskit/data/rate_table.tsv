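# Relative-rate test inputs: unique amino-acid substitution counts per
# lineage, polarised with the Tasmanian devil (marsupial) outgroup over
# the GCKR protein alignment. chi_square/p as originally reported, kept
# for cross-checking only (the package recomputes both).
lineage_a	lineage_b	outgroup	n_a	n_b	chi_square_reported	p_reported
Human	Dog	Tasmanian_devil	22	15	1.32	0.25
Human	Panda	Tasmanian_devil	23	12	3.46	0.06
Human	Horse	Tasmanian_devil	21	19	0.1	0.75
Human	Pig	Tasmanian_devil	18	25	1.14	0.29
Mouse	Dog	Tasmanian_devil	48	10	24.9	<0.01
Mouse	Panda	Tasmanian_devil	52	11	26.68	<0.01
Mouse	Horse	Tasmanian_devil	47	15	16.52	<0.01
Mouse	Pig	Tasmanian_devil	44	21	8.14	<0.01
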
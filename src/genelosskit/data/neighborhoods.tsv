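# Gene-neighborhood maps around the GCKR locus (relative order and
# orientation only; coordinates are ordinal placeholders, not to scale).
# Compiled from Ensembl release 69 annotation. Human stands for the
# mammalian arrangement; chicken for the avian arrangement (FNDC4 and
# ZNF512 adjacent on one assembled fragment, no GCKR between them);
# shrew/platypus/anole rows reflect the short disjoint fragments
# recovered for those draft assemblies. Columns:
# species	fragment	symbol	strand	start
Human	Chr2	IFT172	-	100000
Human	Chr2	FNDC4	+	150000
Human	Chr2	GCKR	+	200000
Human	Chr2	ZNF512	+	250000
Human	Chr2	C2ORF16	+	300000
Chicken	chr4_frag	IFT172	-	10000
Chicken	chr4_frag	FNDC4	+	20000
Chicken	chr4_frag	ZNF512	+	30000
Chicken	chr4_frag	C2ORF16	+	40000
Chinese_softshell_turtle	JH210441.1	GCKR	+	6448
Chinese_softshell_turtle	JH211948.1	GCKR	+	1000
Chinese_softshell_turtle	JH211948.1	ZNF512	+	20000
Coelacanth	JH127635.1	FNDC4	+	100000
Coelacanth	JH127635.1	LDLRAP1	-	150000
Coelacanth	JH127635.1	GCKR	+	202083
Coelacanth	JH127635.1	PTK6	-	250000
Coelacanth	JH127635.1	BLK	+	300000
Zebrafish	Chr17	IFT172	-	5500000
Zebrafish	Chr17	FNDC4	+	5600000
Zebrafish	Chr17	GCKR	+	5624859
Zebrafish	Chr17	PTK6	-	5700000
Takifugu	scaffold_64	XKR6	-	650000
Takifugu	scaffold_64	GCKR	+	713339
Takifugu	scaffold_64	FNDC4	-	750000
Shrew	frag_a	FNDC4	+	100
Shrew	frag_b	ZNF512	+	100
Platypus	frag_a	FNDC4	+	500
Platypus	frag_b	ZNF512	-	300
Anole_lizard	frag_a	FNDC4	+	1000
Anole_lizard	frag_b	ZNF512	+	2000
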
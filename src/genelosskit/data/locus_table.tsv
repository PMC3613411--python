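# Vertebrate GCKR locus coordinates (1-based inclusive browser spans).
# Compiled from Ensembl/PreEnsembl release 69 and NCBI (August 2012).
# status: found = genomic span identified; not_found = no GCKR-like
# sequence in the assembly; cdna_only = species represented by a cDNA.
# Coordinates are transcribed as published; minus-strand spans may have
# start > end and are normalised on load.
species	contig	start	end	status
Human	Chr2	27719709	27746554	found
Chimpanzee	Chr2A	27882887	27909760	found
Gorilla	Chr2a	27973322	28000831	found
Orangutan	Chr2a	84605694	84632388	found
Gibbon	GL397331.1	6798770	6825699	found
Baboon	Contig312330_Contig468503	252057	274688	found
Macaque	Chr13	27491384	27514309	found
Squirrel_monkey	JH378252.1	3026699	3052421	found
Marmoset	Chr14	80920115	80945184	found
Marmoset	Chr14b	8215977	82166805	found
Marmoset	GL285667.1	14860	21407	found
Marmoset	GL289329.1	2701	8499	found
Tarsier	scaffold_142375	1	6848	found
Bushbaby	GL873541.1	18431947	18458466	found
Mouse_lemur	GeneScaffold_1280	170174	180857	found
Mouse_lemur	scaffold_9408	44808	49358	found
Mouse	Chr5	31599954	31629673	found
Rat	Chr6	36176192	36204485	found
Chinese_hamster	JH000049	3040662	3062034	found
Kangaroo_rat	GeneScaffold_1944	64619	93530	found
Guinea_pig	scaffold_18	9315790	9341258	found
Squirrel	JH393303	5080559	5101892	found
Pika	GeneScaffold_1353	89382	113541	found
Rabbit	Chr2	158578950	158598892	found
Cow	Chr11	72154947	72176344	found
Sheep	Chr3	36829349	36855060	found
Dolphin	GeneScaffold_1519	243720	266976	found
Pig	Chr3	118796212	118823097	found
Alpaca	GeneScaffold_2392	230396	239542	found
Horse	Chr15	68799209	68819071	found
Dog	Chr17	21434251	21459913	found
Cat	ChrA3	120477725	120487528	found
Ferret	GL897010.1	4462918	4658018	found
Panda	GL192369.1	463160	487028	found
Little_brown_bat	GL430052	860474	888947	found
Flying_fox_bat	GeneScaffold_1035	519562	527386	found
Tree_shrew	GeneScaffold_1539	218507	244816	found
Hedgehog	GeneScaffold_2521	113709	138867	found
Shrew	-	0	0	not_found
Elephant	scaffold_20	41160463	41182623	found
Hyrax	GeneScaffold_2165	16762	42556	found
Lesser_hedgehog_tenrec	GeneScaffold_9143	353017	423957	found
Armadillo	GeneScaffold_3428	67859	94885	found
Sloth	GeneScaffold_3794	42395	42809	found
Sloth	scaffold_170360	376	835	found
Sloth	scaffold_83977	28	3734	found
Opossum	Chr1	508848942	508873322	found
Wallaby	GeneScaffold_1196	275	7845	found
Tasmanian_devil	GL856719.1	1420689	1458490	found
Platypus	-	0	0	not_found
Anole_lizard	-	0	0	not_found
Painted_turtle	JH585650.1	8656	43647	found
Chinese_softshell_turtle	JH210441.1	6448	7388	found
Chinese_softshell_turtle	JH211948.1	132429	114901	found
Chicken	-	0	0	not_found
Turkey	-	0	0	not_found
Zebra_finch	-	0	0	not_found
Budgerigar	-	0	0	not_found
Duck	-	0	0	not_found
Western_clawed_frog	GL176436.1	2467	2564	found
Western_clawed_frog	GL175638.1	1885	7075	found
Western_clawed_frog	GL181463.1	68	7426	found
Western_clawed_frog	GL175969.1	6442	11214	found
African_clawed_frog	-	0	0	cdna_only
Coelacanth	JH127635.1	202083	223756	found
Cod	-	0	0	not_found
Takifugu	scaffold_64	713339	722055	found
Medaka	Chr2	24524153	24535721	found
Stickleback	groupI	23443090	23447491	found
Tetraodon	Chr3	4336678	4340938	found
Zebrafish	Chr17	5624859	5639741	found
Tilapia	GL831144.1	2399129	2414317	found
Platyfish	JH556962.1	106171	111589	found
Spotted_gar	LG1	45522798	45550720	found
Lamprey	GL476557	253805	279336	found
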
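# Per-species GCKR gene status categories.
# Compiled from Ensembl/PreEnsembl release 69 genome assemblies.
# INTACT = full-length ORF with canonical splice sites;
# POTENTIALLY_INTACT = no or one disrupting mutation but incomplete
# evidence (missing exons or a possible sequencing error);
# INACTIVATED = two or more coding-sequence-disrupting mutations;
# DELETED = no GCKR-like sequence found in the assembly.
species	status
Human	INTACT
Chimpanzee	INTACT
Gorilla	INTACT
Orangutan	INTACT
Gibbon	INTACT
Macaque	INTACT
Baboon	INTACT
Mouse_lemur	INTACT
Mouse	INTACT
Rat	INTACT
Chinese_hamster	INTACT
Guinea_pig	INTACT
Rabbit	INTACT
Pig	INTACT
Horse	INTACT
Dog	INTACT
Panda	INTACT
Elephant	INTACT
Tasmanian_devil	INTACT
African_clawed_frog	INTACT
Spotted_gar	INTACT
Squirrel_monkey	POTENTIALLY_INTACT
Marmoset	POTENTIALLY_INTACT
Bushbaby	POTENTIALLY_INTACT
Kangaroo_rat	POTENTIALLY_INTACT
Squirrel	POTENTIALLY_INTACT
Pika	POTENTIALLY_INTACT
Tree_shrew	POTENTIALLY_INTACT
Opossum	POTENTIALLY_INTACT
Wallaby	POTENTIALLY_INTACT
Painted_turtle	POTENTIALLY_INTACT
Chinese_softshell_turtle	POTENTIALLY_INTACT
Western_clawed_frog	POTENTIALLY_INTACT
Coelacanth	POTENTIALLY_INTACT
Takifugu	POTENTIALLY_INTACT
Medaka	POTENTIALLY_INTACT
Stickleback	POTENTIALLY_INTACT
Tetraodon	POTENTIALLY_INTACT
Zebrafish	POTENTIALLY_INTACT
Tilapia	POTENTIALLY_INTACT
Platyfish	POTENTIALLY_INTACT
Lamprey	POTENTIALLY_INTACT
Tarsier	INACTIVATED
Cow	INACTIVATED
Sheep	INACTIVATED
Dolphin	INACTIVATED
Alpaca	INACTIVATED
Cat	INACTIVATED
Ferret	INACTIVATED
Little_brown_bat	INACTIVATED
Flying_fox_bat	INACTIVATED
Hedgehog	INACTIVATED
Hyrax	INACTIVATED
Lesser_hedgehog_tenrec	INACTIVATED
Sloth	INACTIVATED
Armadillo	INACTIVATED
Shrew	DELETED
Platypus	DELETED
Anole_lizard	DELETED
Chicken	DELETED
Turkey	DELETED
Zebra_finch	DELETED
Budgerigar	DELETED
Duck	DELETED
Cod	DELETED
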
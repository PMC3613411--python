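[Consensus vertebrate phylogeny of the surveyed genomes, transcribed from the Ensembl release-69 species tree; rooted, no branch lengths.]
(Lamprey,((Spotted_gar,(Zebrafish,(Cod,((Stickleback,(Takifugu,Tetraodon)),(Tilapia,(Medaka,Platyfish)))))),(Coelacanth,((Western_clawed_frog,African_clawed_frog),(((Painted_turtle,Chinese_softshell_turtle),(Anole_lizard,(((Chicken,Turkey),Duck),(Zebra_finch,Budgerigar)))),(Platypus,((Opossum,(Wallaby,Tasmanian_devil)),((((Elephant,Hyrax),Lesser_hedgehog_tenrec),(Armadillo,Sloth)),((((Rabbit,Pika),(Squirrel,(Guinea_pig,(Kangaroo_rat,(Chinese_hamster,(Mouse,Rat)))))),(Tree_shrew,((Mouse_lemur,Bushbaby),(Tarsier,((Marmoset,Squirrel_monkey),((Macaque,Baboon),(Gibbon,(Orangutan,(Gorilla,(Human,Chimpanzee)))))))))),((Hedgehog,Shrew),((Little_brown_bat,Flying_fox_bat),((Horse,(Cat,(Dog,(Ferret,Panda)))),(Alpaca,(Pig,((Cow,Sheep),Dolphin)))))))))))))));
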
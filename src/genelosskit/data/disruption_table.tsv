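# Exons bearing inactivating mutations in mammalian GCKR genes
# (19 coding exons; exon numbers are comma-separated lists; '-' = none).
# Compiled from exon-by-exon alignments of Ensembl release 69 genomic
# sequence against the human GCKR gene model.
species	frameshift_exons	splice_exons
Tarsier	10,15,16	16
Squirrel	8	-
Cow	2,5,7,8,15,17,18,19	2,9,10,12,15,18
Sheep	5,6,8,12,18	9,10,12
Dolphin	1,3,4,6,8,9,15,19	1
Alpaca	5,7	1
Cat	2,4,10	2
Ferret	-	9,10,12
Little_brown_bat	2	3
Flying_fox_bat	5,6,8,10,12	5,8,10,11
Hedgehog	1,3,4,17	2
Tree_shrew	4	-
Hyrax	1,3,5,10,11,17	1,3,4,5,7,11,19
Lesser_hedgehog_tenrec	5,7,8,9,13,17,18	5,6,9,13,14,15
Armadillo	8,13,14,15,19	13,15,16,18,19
Sloth	7,13,19	2,4,5,6,7,18
Opossum	12	-
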
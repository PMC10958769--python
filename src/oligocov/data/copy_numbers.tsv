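taxon	copies	note
Ca_Accumulibacter	2	two 16S copies per genome
Defluviicoccus	2	two 16S copies per genome
Tetrasphaera	1	single copy
Ca_Phosphoribacter	1	single copy
Ca_Lutibacillus	1	single copy
Microlunatus	1	single copy
Ca_Contendobacter	1	single copy
Ca_Competibacter	1	single copy
Dechloromonas	4	3-4 copies reported; upper value used
activated_sludge_average	4.1	community-average copy number
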
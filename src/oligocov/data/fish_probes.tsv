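name	sequence	role	target_group	formamide_pct	citation
Acc444	CCCAAGCAATTTCTTCCC	fish_probe	Ca_Accumulibacter	35	clade IA
HAcc466	CATCTACTCAGGGTATTAA	fish_probe	Ca_Accumulibacter	35	clade IA helper
HAcc426	CGCCGAAAGAGCTTTACA	fish_probe	Ca_Accumulibacter	35	clade IA helper
Acc184	GCTCCCAGAACGCAAGGT	fish_probe	Ca_Accumulibacter	35	clade IF
CAcc184	GCTCCCAGAGCGCAAGGT	fish_probe	Ca_Accumulibacter	35	clade IF competitor
Acc119	GGATACGTTCCGATGCTT	fish_probe	Ca_Accumulibacter	35	clade IIA
HAcc99	CTCACCCGTCCGCCACTC	fish_probe	Ca_Accumulibacter	35	clade IIA helper
HAcc139	GCTACGTTATCCCCCACTC	fish_probe	Ca_Accumulibacter	35	clade IIA helper
CAcc119	GGGCACGTTCCGATGCAT	fish_probe	Ca_Accumulibacter	35	clade IIA competitor
Acc623	CCAGCTGGACAGTCTCAA	fish_probe	Ca_Accumulibacter	35	clade IIC
Acc469	CCAGGTACCGTCATCTACACAGGC	fish_probe	Ca_Accumulibacter	30	Ca. Accumulibacter proximus
Acc471	CTCCAGGTACCGTCATCTACACAG	fish_probe	Ca_Accumulibacter	40	Ca. Accumulibacter affinis
Acc1011	GCGAGCACTCCCAGATCTCTC	fish_probe	Ca_Accumulibacter	40	Ca. Accumulibacter propinquus
Acc635	AACTCCAGCCTGGCAGTCTCAAAT	fish_probe	Ca_Accumulibacter	30	Ca. Accumulibacter regalis
Acc470	TTCGGGTACCGTCATCTACTCAGG	fish_probe	Ca_Accumulibacter	30	Ca. Accumulibacter aalborgensis
Acc471_2	AGTCGGGTACCGTCATCTACACAG	fish_probe	Ca_Accumulibacter	30	Ca. Accumulibacter iunctus/similis
PAO846	GTTAGCTACGGCACTAAAAGG	fish_probe	Ca_Accumulibacter	35	PAOmix member
PAO462	CCGTCATCTACWCAGGGTATTAAC	fish_probe	Ca_Accumulibacter	35	PAOmix member
PAO651	CCCTCTGCCAAACTCCAG	fish_probe	Ca_Accumulibacter	35	PAOmix member
Tet1-266	CCCGTCGTCGCCTGTAGC	fish_probe	Tetrasphaera	25	clade 1
Tet2-174	GCTCCGTCTCGTATCCGG	fish_probe	Tetrasphaera	20	clade 2
Tet2-831	TCGTGAAATGAGTCCCAC	fish_probe	Tetrasphaera	10	clade 2
Tet2-842	GCGGCACAGAACTCGTGA	fish_probe	Tetrasphaera	30	clade 2
Tet2-87	TCGCCACTGATCAGGAGA	fish_probe	Tetrasphaera	10	clade 2
Tet2-892	TAGTTAGCCTTGCGGCCG	fish_probe	Tetrasphaera	5	clade 2
Tet3-19	CAGCGTTCGTCCTACACA	fish_probe	Tetrasphaera	0	clade 3
Tet3-654	GGTCTCCCCTACCATACT	fish_probe	Tetrasphaera	35	clade 3
Elo1-1250	CGCGATTTCGCAGCCCTT	fish_probe	Tetrasphaera	20	clade 1
Actino-221	CGCAGGTCCATCCCAGAC	fish_probe	Tetrasphaera	30	actinobacterial PAO, cocci
Tet2-823	TGAGACCCGCACCTAGTT	fish_probe	Tetrasphaera	30	clade 2
Actino-1011	TTGCGGGGCACCCATCTCT	fish_probe	Tetrasphaera	30	Epbr19, Ebpr20
Tetra67	AGCAAGCTCCTCCGTCACCG	fish_probe	Tetrasphaera	40	corrected sequence; original publication may have omitted three bases
Tetra732	AGTGGTGGCCCAGAGACCTG	fish_probe	Tetrasphaera	40	midas_s_299 and relatives
Tetra183	TAGAGATGCCTCTCCGTCTC	fish_probe	Tetrasphaera	30	Tetrasphaera genus
Actino-658	TCCGGTCTCCCCTACCAT	fish_probe	Ca_Phosphoribacter	40	rod morphotype; mainly Ca. Phosphoribacter
Phos741	TTCTCAGCGTCAGTTGTGGCCC	fish_probe	Ca_Phosphoribacter	30	
Phos601	GGTTGAGCCTCGGATTTTCACTGC	fish_probe	Ca_Phosphoribacter	30	Ca. Phosphoribacter hodrii
Luti617	CCCACTGCAAGTCCGGAATTGAGT	fish_probe	Ca_Lutibacillus	30	midas_s_45
TFO_DF862	AGCTAAGCTCCCCGACAT	fish_probe	Defluviicoccus	35	Defluviicoccus vanus, cluster I
TFO_DF618	GCCTCACTTGTCTAACCG	fish_probe	Defluviicoccus	25	cluster I
TFO_DF218	GAAGCCTTTGCCCCTCAG	fish_probe	Defluviicoccus	25	cluster I
DF1004	TAAGTTTCCTCAAGCCGC	fish_probe	Defluviicoccus	35	cluster III, C17 & C23 clones
DF1013	GAACTGAAGGCTCGAGTTTC	fish_probe	Defluviicoccus	35	cluster III, A40 & B29 clones
DF198	ATCCCAGGGCAACATAGTCT	fish_probe	Defluviicoccus	35	Ca. Monilibacter batavus-related
DF181B	CTTTGCCCCTCAAGGCAC	fish_probe	Defluviicoccus	30	cluster IV
DF181A	CTTTCCCTCACAAGGCAC	fish_probe	Defluviicoccus	30	cluster IV
DF1020	CCGGCCGAACCGACTCCC	fish_probe	Defluviicoccus	35	cluster II
DF988	GATACGACGCCCATGTCAAGGG	fish_probe	Defluviicoccus	35	cluster II
DCMAG455	CAGGTATTAGCTGATGCG	fish_probe	Dechloromonas	30	Dechloromonas agitata
DEMFE455	AGGGTATTAACCCATGCG	fish_probe	Dechloromonas	30	Ferribacterium limneticum, few Dechloromonas spp.
Bet135	ACGTTATCCCCCACTCAATGG	fish_probe	Dechloromonas	45	Skagen clones and related Rhodocyclaceae
Dech453	GGGTATTCACCCATGCGA	fish_probe	Dechloromonas	35	Dechloromonas genus
Dech443	ACCCATGCATTTTCTTCCCGG	fish_probe	Dechloromonas	35	Dechloromonas sub-group
CPB654	TCCTCTAGCCCACTC	fish_probe	Ca_Competibacter	35	Competibacter lineage
GAO431	TCCCCGCCTAAAGGGCTT	fish_probe	Ca_Competibacter	35	Ca. Competibacter phosphatis
GAO989	TTCCCCGGATGTCAAGGC	fish_probe	Ca_Competibacter	35	Ca. Competibacter phosphatis
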
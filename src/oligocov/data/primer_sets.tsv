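name	sequence	role	target_group	formamide_pct	citation	forward	reverse	min_length	max_length
27F	AGRGTTTGATCMTGGCTCAG	primer_forward	universal		degenerate 27F				
27Fp	AGAGTTTGATCCTGGCTCAG	primer_forward	universal		non-degenerate 27F (27F')				
338F	ACTCCTACGGGAGGCAGCAG	primer_forward	universal						
341F	CCTACGGGNGGCWGCAG	primer_forward	universal						
515F	GTGYCAGCMGCCGCGGTAA	primer_forward	universal						
520F	AYTGGGYDTAAAGNG	primer_forward	universal						
799F	AACMGGATTAGATACCCKG	primer_forward	universal						
533R	TTACCGCGGCTGCTGGCAC	primer_reverse	universal						
534R	TTACCGCGGCTGCTGGCAC	primer_reverse	universal						
802R	TACNVGGGTATCTAATCC	primer_reverse	universal						
806R	GGACTACNVGGGTWTCTAAT	primer_reverse	universal						
907R	CCGTCAATTCMTTTRAGTTT	primer_reverse	universal						
926R	CCGYCAATTYMTTTRAGTTT	primer_reverse	universal						
1193R	ACGTCATCCCCACCTTCC	primer_reverse	universal						
27F-533R		primer_set	V1-V3			27F	533R	300	800
27Fp-533R		primer_set	V1-V3			27Fp	533R	300	800
27F-534R		primer_set	V1-V3			27F	534R	300	800
27Fp-534R		primer_set	V1-V3			27Fp	534R	300	800
338F-806R		primer_set	V3-V4			338F	806R	250	700
341F-806R		primer_set	V3-V4			341F	806R	250	700
520F-802R		primer_set	V4			520F	802R	150	600
515F-806R		primer_set	V4			515F	806R	150	600
515F-907R		primer_set	V4-V5			515F	907R	200	700
515F-926R		primer_set	V4-V5			515F	926R	200	700
799F-1193R		primer_set	V5-V7			799F	1193R	200	700
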
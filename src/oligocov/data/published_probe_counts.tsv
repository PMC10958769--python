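kind	oligo_or_mix	database	group	n_target	n_hit	printed_coverage_pct	text_coverage_pct	consistent	note
probe	Acc444	silva	Ca_Accumulibacter	86	18	20.9		True	
probe	HAcc466	silva	Ca_Accumulibacter	86	18	20.9		True	
probe	HAcc426	silva	Ca_Accumulibacter	86	26	30.2		True	
probe	Acc184	silva	Ca_Accumulibacter	86	8	9.3		True	
probe	CAcc184	silva	Ca_Accumulibacter	86	28	32.6		True	
probe	Acc119	silva	Ca_Accumulibacter	86	5	5.8		True	
probe	HAcc99	silva	Ca_Accumulibacter	86	33	38.4		True	
probe	HAcc139	silva	Ca_Accumulibacter	86	29	33.7		True	
probe	CAcc119	silva	Ca_Accumulibacter	86	17	19.8		True	
probe	Acc623	silva	Ca_Accumulibacter	86	5	5.8		True	
probe	Acc469	silva	Ca_Accumulibacter	86	1	1.2		True	
probe	Acc471	silva	Ca_Accumulibacter	86	27	31.4		True	
probe	Acc1011	silva	Ca_Accumulibacter	86	5	5.8		True	
probe	Acc635	silva	Ca_Accumulibacter	86	3	3.5		True	
probe	Acc470	silva	Ca_Accumulibacter	86	15	17.4		True	
probe	Acc471_2	silva	Ca_Accumulibacter	86	7	8.1		True	
probe	PAO846	silva	Ca_Accumulibacter	86	73	84.9		True	
probe	PAO462	silva	Ca_Accumulibacter	86	32	37.2		True	
probe	PAO651	silva	Ca_Accumulibacter	86	61	70.9		True	
probe	Tet1-266	silva	Tetrasphaera	51	0	0.0		True	
probe	Tet2-174	silva	Tetrasphaera	51	4	7.8		True	
probe	Tet2-831	silva	Tetrasphaera	51	9	17.6		True	
probe	Tet2-842	silva	Tetrasphaera	51	10	19.6		True	
probe	Tet2-87	silva	Tetrasphaera	51	1	2.0		True	
probe	Tet2-892	silva	Tetrasphaera	51	0	0.0		True	
probe	Tet3-19	silva	Tetrasphaera	51	0	0.0		True	
probe	Tet3-654	silva	Tetrasphaera	51	1	2.0		True	
probe	Elo1-1250	silva	Tetrasphaera	51	10	19.6		True	
probe	Actino-221	silva	Tetrasphaera	51	1	2.0		True	
probe	Tet2-823	silva	Tetrasphaera	51	0	0.0		True	
probe	Actino-1011	silva	Tetrasphaera	51	20	39.2		True	
probe	Tetra67	silva	Tetrasphaera	51	3	5.9		True	
probe	Tetra732	silva	Tetrasphaera	51	3	5.9		True	
probe	Tetra183	silva	Tetrasphaera	51	18	35.3		True	
probe	Actino-658	silva	Ca_Phosphoribacter	28	15	60.0		False	printed figure implies a denominator of 25; the stated group size is 28
probe	Phos741	silva	Ca_Phosphoribacter	28	6	21.4		True	
probe	Phos601	silva	Ca_Phosphoribacter	28	6	21.4		True	
probe	Luti617	silva	Ca_Lutibacillus	5	3	60.0		True	
probe	TFO_DF862	silva	Defluviicoccus	75	4	5.3		True	
probe	TFO_DF618	silva	Defluviicoccus	75	4	5.3		True	
probe	TFO_DF218	silva	Defluviicoccus	75	7	9.3		True	
probe	DF1004	silva	Defluviicoccus	75	1	1.3		True	
probe	DF1013	silva	Defluviicoccus	75	1	1.3		True	
probe	DF198	silva	Defluviicoccus	75	3	4.0		True	
probe	DF181B	silva	Defluviicoccus	75	3	4.0		True	
probe	DF181A	silva	Defluviicoccus	75	1	1.3		True	
probe	DF1020	silva	Defluviicoccus	75	7	9.3		True	
probe	DF988	silva	Defluviicoccus	75	8	10.7		True	
probe	DCMAG455	silva	Dechloromonas	181	6	3.3		True	
probe	DEMFE455	silva	Dechloromonas	181	40	22.1		True	
probe	Bet135	silva	Dechloromonas	181	16	8.9		False	16/181 rounds to 8.8, not the printed 8.9
probe	Dech453	silva	Dechloromonas	181	5	2.8		True	
probe	Dech443	silva	Dechloromonas	181	6	3.3		True	
probe	CPB654	silva	Ca_Competibacter	95	83	87.4		True	
probe	GAO431	silva	Ca_Competibacter	95	48	57.0	50.5	False	table prints 57 but the running text computes 50.5 from 48/95
probe	GAO989	silva	Ca_Competibacter	95	50	59.0	52.6	False	table prints 59 but the running text computes 52.6 from 50/95
probe	Acc444	midas	Ca_Accumulibacter	218	76	34.9		True	
probe	HAcc466	midas	Ca_Accumulibacter	218	60	27.6		False	60/218 rounds to 27.5, not the printed 27.6
probe	HAcc426	midas	Ca_Accumulibacter	218	92	42.2		True	
probe	Acc184	midas	Ca_Accumulibacter	218	32	14.7		True	
probe	CAcc184	midas	Ca_Accumulibacter	218	95	43.6		True	
probe	Acc119	midas	Ca_Accumulibacter	218	18	8.3		True	
probe	HAcc99	midas	Ca_Accumulibacter	218	111	50.9		True	
probe	HAcc139	midas	Ca_Accumulibacter	218	97	44.5		True	
probe	CAcc119	midas	Ca_Accumulibacter	218	18	8.3		True	
probe	Acc623	midas	Ca_Accumulibacter	218	1	0.5		True	
probe	Acc469	midas	Ca_Accumulibacter	218	2	0.9		True	
probe	Acc471	midas	Ca_Accumulibacter	218	40	18.3		True	
probe	Acc1011	midas	Ca_Accumulibacter	218	7	3.2		True	
probe	Acc635	midas	Ca_Accumulibacter	218	10	4.6		True	
probe	Acc470	midas	Ca_Accumulibacter	218	65	29.8		True	
probe	Acc471_2	midas	Ca_Accumulibacter	218	21	9.6		True	
probe	PAO846	midas	Ca_Accumulibacter	218	210	96.3		True	
probe	PAO462	midas	Ca_Accumulibacter	218	103	47.2		True	
probe	PAO651	midas	Ca_Accumulibacter	218	187	85.8		True	
probe	Tet1-266	midas	Tetrasphaera	157	0	0.0		True	
probe	Tet2-174	midas	Tetrasphaera	157	12	7.6		True	
probe	Tet2-831	midas	Tetrasphaera	157	24	15.3		True	
probe	Tet2-842	midas	Tetrasphaera	157	37	23.6		True	
probe	Tet2-87	midas	Tetrasphaera	157	7	4.5		True	
probe	Tet2-892	midas	Tetrasphaera	157	0	0.0		True	
probe	Tet3-19	midas	Tetrasphaera	157	0	0.0		True	
probe	Tet3-654	midas	Tetrasphaera	157	0	0.0		True	
probe	Elo1-1250	midas	Tetrasphaera	157	44	28.0		True	
probe	Actino-221	midas	Tetrasphaera	157	5	3.2		True	
probe	Tet2-823	midas	Tetrasphaera	157	0	0.0		True	
probe	Actino-1011	midas	Tetrasphaera	157	65	41.4		True	
probe	Tetra67	midas	Tetrasphaera	157	35	22.3		True	
probe	Tetra732	midas	Tetrasphaera	157	15	9.6		True	
probe	Tetra183	midas	Tetrasphaera	157	92	58.6		True	
probe	Actino-658	midas	Ca_Phosphoribacter	74	26	35.1		True	
probe	Phos741	midas	Ca_Phosphoribacter	74	38	51.4		True	
probe	Phos601	midas	Ca_Phosphoribacter	74	7	9.5		True	
probe	Luti617	midas	Ca_Lutibacillus	15	5	33.3		True	
probe	TFO_DF862	midas	Defluviicoccus	164	18	11.0		True	
probe	TFO_DF618	midas	Defluviicoccus	164	4	2.4		True	
probe	TFO_DF218	midas	Defluviicoccus	164	30	18.3		True	
probe	DF1004	midas	Defluviicoccus	164	4	2.4		True	
probe	DF1013	midas	Defluviicoccus	164	7	4.3		True	
probe	DF198	midas	Defluviicoccus	164	16	9.8		True	
probe	DF181B	midas	Defluviicoccus	164	8	4.9		True	
probe	DF181A	midas	Defluviicoccus	164	2	1.2		True	
probe	DF1020	midas	Defluviicoccus	164	38	23.2		True	
probe	DF988	midas	Defluviicoccus	164	29	17.7		True	
probe	DCMAG455	midas	Dechloromonas	387	25	6.5		True	
probe	DEMFE455	midas	Dechloromonas	387	83	21.4		True	
probe	Bet135	midas	Dechloromonas	387	60	15.5		True	
probe	Dech453	midas	Dechloromonas	387	3	0.8		True	
probe	Dech443	midas	Dechloromonas	387	31	8.0		True	
probe	CPB654	midas	Ca_Competibacter	429	388	90.4		True	
probe	GAO431	midas	Ca_Competibacter	429	219	51.0		True	
probe	GAO989	midas	Ca_Competibacter	429	215	50.1		True	
mix	PAOmix	silva	Ca_Accumulibacter	86	79	91.9		True	seven target sequences uncovered
mix	GAOmix	silva	Ca_Competibacter	95	62	65.3		True	thirty-three target sequences uncovered
mix	CPB654-family	silva	Ca_Competibacteraceae	118	105	89.0		True	family-level evaluation of CPB654
mix	all-probes	silva	Ca_Accumulibacter	86	83	96.5		True	3 sequences (3.5%) uncovered by any probe
mix	all-probes	midas	Ca_Accumulibacter	218	215	98.6		True	3 sequences (1.4%) uncovered by any probe
mix	all-probes	silva	Tetrasphaera	51	37	72.5		True	14 sequences (27.5%) uncovered by any probe
mix	all-probes	midas	Tetrasphaera	157	134	85.4		True	23 sequences (14.6%) uncovered by any probe
mix	all-probes	silva	Dechloromonas	181	65	35.9		True	116 sequences (64.1%) uncovered by any probe
mix	all-probes	midas	Dechloromonas	387	178	46.0		True	209 sequences (54.0%) uncovered by any probe
mix	all-probes	midas	Ca_Competibacter	429	388	90.4		True	41 sequences (9.6%) uncovered by any probe
mix	all-probes	midas	Defluviicoccus	164	93	56.7		True	71 sequences (43.3%) uncovered by any probe
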
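# Published midgut screen: multipass-TM DEGs with transport-consistent
# expression patterns (heme_excess over heme_deficient contrast).
gene_id	log2fc	q_value	tm_count
AAEL000859	-1.3184	1.40E-08	2
AAEL019869	-1.2359	1.05E-05	2
AAEL002557	-1.1718	9.42E-07	12
AAEL024460	-1.1243	0.00115	4
AAEL020936	-1.0454	6.14E-05	2
AAEL021618	-1.032	0.02785	2
AAEL024267	-0.982	0.00343	2
AAEL003619	-0.9543	0.00042	12
AAEL001938	-0.8521	0.00624	17
AAEL007191	-0.8341	0.00233	10
AAEL010905	-0.826	0.00082	6
AAEL005013	-0.789	0.00148	2
AAEL012440	-0.7835	4.60E-05	10
AAEL001495	-0.7597	0.01199	6
AAEL004513	-0.7512	0.00589	3
AAEL008664	-0.7068	0.00188	2
AAEL006480	-0.7036	0.00573	3
AAEL014355	-0.6857	0.04023	2
AAEL003618	-0.6854	0.04341	12
AAEL009531	-0.6551	0.00052	14
AAEL012226	-0.6385	0.02752	4
AAEL009112	-0.6322	0.03157	2
AAEL011918	-0.6194	0.02778	2
AAEL027190	-0.5945	0.00269	8
AAEL000461	-0.5927	0.00551	3
AAEL000417	-0.5895	0.02177	12
AAEL003318	-0.5479	0.01182	10
AAEL021771	-0.5258	0.03568	3
AAEL006855	0.469	0.04311	10
AAEL012395	0.5554	0.02778	12
AAEL023104	0.6348	0.02177	4
AAEL027424	0.7912	0.00758	8
AAEL018150	0.8105	0.03276	13
AAEL022465	0.8262	0.02191	3
AAEL028119	0.8301	0.01236	2
AAEL002129	1.0183	3.69E-05	2
AAEL005043	1.1916	8.42E-05	17
AAEL002599	1.2418	3.07E-05	2
AAEL021284	1.6055	1.95E-06	2
AAEL029008	1.7825	5.04E-12	2
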
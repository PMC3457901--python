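# Per-locus McDonald-Kreitman count data for 54 Daphnia pulex loci
# (30 putative immune, 24 non-immune), with D. parvula or D. arenata as
# outgroup.  Columns: polymorphism counts per species (pn/ps), fixed
# differences (dn/ds), basepairs sequenced, number of diploid individuals
# sequenced per species.  include_multilocus = 0 marks loci excluded from
# the multilocus model: D. arenata-outgroup loci (unequal divergence
# time) and the two hyperdiverse loci Caspase_8 and Chitinase_17.
locus_id	class	outgroup	n_ind_in	n_ind_out	bp	pn_in	ps_in	pn_out	ps_out	dn	ds	include_multilocus
Actin	nonimmune	D_parvula	11	2	421	0	4	0	0	0	8	1
Caspase_1	nonimmune	D_parvula	11	4	707	0	12	0	0	0	8	1
Caspase_2	nonimmune	D_parvula	7	1	655	28	18	4	9	1	0	1
Caspase_3	nonimmune	D_parvula	5	1	529	10	13	1	1	20	12	1
Caspase_4	nonimmune	D_parvula	11	3	513	22	10	7	7	10	4	1
Caspase_5	nonimmune	D_parvula	9	2	587	16	14	1	1	7	16	1
Caspase_6	nonimmune	D_parvula	8	3	547	27	8	1	1	12	7	1
Chitinase_15	nonimmune	D_parvula	11	3	877	5	17	11	5	6	8	1
Chitinase_16	nonimmune	D_parvula	11	4	931	3	12	7	3	9	19	1
Chitinase_17	nonimmune	D_parvula	10	3	909	48	71	3	1	13	18	0
Eukaryotic_translation_initiation_factor_2g	nonimmune	D_parvula	10	3	1237	0	9	0	2	0	6	1
Enolase	nonimmune	D_parvula	10	4	336	0	2	0	0	0	12	1
Fumerate	nonimmune	D_parvula	10	1	1103	2	13	0	2	3	28	1
Glutamine-oxaloacetic_transaminase	nonimmune	D_parvula	10	4	777	0	15	1	1	3	17	1
Glyceraldehyde_3-phosphate_dehydrogenase	nonimmune	D_parvula	11	4	701	0	4	0	0	0	9	1
Lactose_dehydrogenase	nonimmune	D_parvula	11	2	840	4	18	0	0	0	13	1
Mannose_phosphase_isomerase	nonimmune	D_parvula	9	3	751	2	4	1	0	0	13	1
Phosphoglucose_isomerase	nonimmune	D_parvula	11	2	1387	9	49	1	4	2	16	1
Phosphoglycerate_mutase	nonimmune	D_parvula	8	1	1184	4	56	2	0	3	17	1
Scavenger_5	nonimmune	D_parvula	9	3	1440	1	30	3	11	5	27	1
Scavenger_6	nonimmune	D_parvula	7	3	1119	7	21	5	7	6	16	1
Ultraspiracle	nonimmune	D_parvula	10	4	336	0	2	0	0	0	12	1
Chitinase_1	nonimmune	D_arenata	8	1	885	12	27	0	0	5	7	0
Chitinase_9	nonimmune	D_arenata	6	1	908	18	43	0	1	2	2	0
Caspase_8	immune	D_parvula	2	2	672	55	27	1	0	33	11	0
Dicer2	immune	D_parvula	3	1	265	5	8	0	0	10	6	1
Dorsal	immune	D_parvula	11	4	624	0	12	0	0	0	8	1
Galectin_1	immune	D_parvula	11	2	715	2	9	0	4	5	8	1
Galectin_2	immune	D_parvula	10	4	864	1	6	0	0	4	18	1
Gemini	immune	D_parvula	11	2	1083	2	26	1	3	2	14	1
Gram-negative_binding_protein_1	immune	D_parvula	11	3	825	5	9	0	1	18	17	1
Gram-negative_binding_protein_10	immune	D_parvula	11	4	638	0	5	1	7	2	11	1
Gram-negative_binding_protein_11	immune	D_parvula	11	3	787	8	20	2	3	8	14	1
Gram-negative_binding_protein_2	immune	D_parvula	10	2	748	5	18	5	3	1	1	1
Gram-negative_binding_protein_6	immune	D_parvula	10	2	836	5	11	2	1	5	10	1
IMD	immune	D_parvula	10	3	489	10	12	1	2	5	10	1
MyD88	immune	D_parvula	11	3	834	3	11	3	2	13	21	1
Nitric_oxide_synthase_1	immune	D_parvula	11	3	662	1	14	0	1	2	4	1
Nitric_oxide_synthase_2	immune	D_parvula	9	2	549	8	6	2	1	5	15	1
Pelle	immune	D_parvula	12	2	797	0	6	1	2	3	9	1
Prophenol_Oxidase	immune	D_parvula	5	2	1224	13	15	2	9	0	0	1
Scavenger_2	immune	D_parvula	10	2	1463	24	18	7	2	16	22	1
Scavenger_4	immune	D_parvula	6	3	841	10	42	1	0	5	12	1
Stat	immune	D_parvula	11	3	844	0	9	0	5	0	5	1
TEP_1	immune	D_parvula	6	2	1067	1	7	0	2	8	11	1
TEP_2	immune	D_parvula	4	2	865	4	18	0	3	3	21	1
TEP_3	immune	D_parvula	9	3	1013	2	26	1	6	3	20	1
Tequila	immune	D_parvula	3	1	834	2	24	0	7	0	1	1
Toll_1	immune	D_parvula	9	4	468	1	6	1	0	18	7	1
Toll_2	immune	D_parvula	10	4	836	5	10	0	0	8	18	1
Toll_3	immune	D_parvula	9	4	523	1	14	0	3	0	5	1
Scavenger_3	immune	D_arenata	5	1	552	7	25	0	0	5	2	0
Gram-negative_binding_protein_7	immune	D_arenata	9	1	788	5	31	0	0	5	10	0
Galectin_3	immune	D_arenata	8	1	974	9	22	0	0	1	5	0
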
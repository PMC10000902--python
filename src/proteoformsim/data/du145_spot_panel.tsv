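# DU145 benchmark spot panel: 36 2D-gel spots covering 11 proteins mutually
# quantified by 2D-DIGE (spot level) and label-free shotgun (canonical-protein
# level). One row per spot. Gene-level quantities (theoretical pI/MW, summed-spot
# CVs, shotgun CVs, LFQ intensity) are printed only on the first spot row of each
# gene, as in the source report; NA elsewhere. lfq_intensity is repeated on every
# row of a gene because it is a gene-level value needed for per-spot pairing.
# spot_id is a corrected unique id; label_as_printed preserves the original spot
# labels including a duplicated "31" (one CAP1 and one GAPDH row, the latter
# presumably 33). excluded_from_correlation marks the CALM1 rows left out of the
# proteoform-to-protein correlations (34 spots / 10 genes enter them).
# Known quirk kept verbatim: YWHAG CV_tech/CV_total printed here (4.5/1.8)
# disagree with the 2.6/5.5 quoted elsewhere in the source narrative.
spot_id	label_as_printed	gene	protein_name	identified_by	ph_range	practical_pi	theoretical_pi	practical_mw_kda	theoretical_mw_kda	dige_cv_tech	dige_sum_cv_tech	dige_cv_total	dige_sum_cv_total	shotgun_cv_tech	shotgun_cv_total	spot_size	lfq_intensity	excluded_from_correlation
1	1	CALM1	Calmodulin-1	2D-WB	4-7	3.66	4.09	14.1	16.8	3.9	33	12.9	34.2	15	55	9.7	218110164	true
2	2	CALM1	Calmodulin-1	MS	4-7	4.09	NA	16.8	NA	62.2	NA	55.4	NA	NA	NA	38.8	218110164	true
3	3	PTGES3	Prostaglandin E synthase 3	MS	4-7	3.79	4.32	20.8	19.2	3.8	5.1	8.6	9.2	33.7	67.6	18.4	23571667	false
4	4	PTGES3	Prostaglandin E synthase 3	2D-WB	4-7	3.87	NA	20.8	NA	6.4	NA	9.8	NA	NA	NA	5.5	23571667	false
5	5	YWHAG	14-3-3 protein gamma	MS	4-7	4.70	4.80	29.1	28.3	4.5	4.5	1.8	1.8	18.8	44.36	25.4	3275800	false
6	6	P4HB	Protein disulfide-isomerase	MS	4-7	4.72	4.76	58.3	57.1	3.3	4.5	3.7	5.5	8.9	63.2	12.7	63695001	false
7	7	P4HB	Protein disulfide-isomerase	MS	4-7	4.76	NA	57.1	NA	2.5	NA	5.0	NA	NA	NA	147	63695001	false
8	8	P4HB	Protein disulfide-isomerase	MS	4-7	4.78	NA	59.5	NA	8.8	NA	9.6	NA	NA	NA	5.9	63695001	false
9	9	P4HB	Protein disulfide-isomerase	MS	4-7	4.84	NA	58.0	NA	3.6	NA	3.7	NA	NA	NA	19.4	63695001	false
10	10	CTSB	Cathepsin B	2D-WB	4-7	5.43	5.88	27.8	37.8	1.5	7.7	11.8	10.1	23.4	39.6	7.9	1219708	false
11	11	CTSB	Cathepsin B	MS	4-7	5.53	NA	26.1	NA	14.4	NA	5.1	NA	NA	NA	3.4	1219708	false
12	12	CTSB	Cathepsin B	MS	4-7	5.54	NA	27.0	NA	7.1	NA	13.5	NA	NA	NA	5.6	1219708	false
13	13	CTSD	Cathepsin D	MS	4-7	5.76	6.10	30.4	43.7	3.1	2.5	6.4	21.2	17.4	60.7	5.2	5884650	false
14	14	CTSD	Cathepsin D	MS	4-7	5.97	NA	28.8	NA	1.9	NA	36.1	NA	NA	NA	24.1	5884650	false
15	15	PKM2	Pyruvate kinase PKM2	MS	4-7	5.80	7.96	59.3	57.9	4.6	6.3	4.6	15.1	27.3	66.0	11.3	22507667	false
16	16	PKM2	Pyruvate kinase PKM2	MS	4-7	6.08	NA	58.3	NA	3.7	NA	5.3	NA	NA	NA	17.8	22507667	false
17	17	PKM2	Pyruvate kinase PKM2	2D-WB	6-9	7.50	NA	57.6	NA	6.8	NA	11.9	NA	NA	NA	104.8	22507667	false
18	18	PKM2	Pyruvate kinase PKM2	MS	6-9	7.75	NA	57.7	NA	8.2	NA	19.7	NA	NA	NA	38.7	22507667	false
19	19	PKM2	Pyruvate kinase PKM2	MS	6-9	7.32	NA	42.0	NA	7.1	NA	42.2	NA	NA	NA	14.6	22507667	false
20	20	PKM2	Pyruvate kinase PKM2	MS	6-9	7.96	NA	57.9	NA	7.9	NA	17.9	NA	NA	NA	391.3	22507667	false
21	21	PKM2	Pyruvate kinase PKM2	MS	6-9	8.20	NA	57.4	NA	5.6	NA	4.0	NA	NA	NA	9.3	22507667	false
22	22	EIF4A1	Eukaryotic initiation factor 4A-I	MS	4-7	5.81	5.32	48.6	46.2	3.0	2	13.2	11.8	11.0	48.8	80.6	41301834	false
23	23	EIF4A1	Eukaryotic initiation factor 4A-I	MS	4-7	5.90	NA	47.8	NA	2.7	NA	10.5	NA	NA	NA	70	41301834	false
24	24	TALDO1	Transaldolase	2D-WB	4-7	6.33	6.36	39.1	37.5	2.3	4.6	16.0	15.9	15.0	51.1	9.7	14659166	false
25	25	TALDO1	Transaldolase	MS	4-7	6.82	NA	38.0	NA	4.2	NA	14.4	NA	NA	NA	19.1	14659166	false
26	26	TALDO1	Transaldolase	MS	4-7	7.32	NA	39.2	NA	7.4	NA	16.9	NA	NA	NA	20.3	14659166	false
27	27	CAP1	Adenylyl cyclase-associated protein 1	MS	6-9	6.83	8.24	54.9	51.9	4.0	5.9	19.3	12.9	21.3	47.9	6.2	18092833	false
28	28	CAP1	Adenylyl cyclase-associated protein 1	2D-WB	6-9	6.95	NA	55.1	NA	7.8	NA	8.4	NA	NA	NA	10.9	18092833	false
29	29	CAP1	Adenylyl cyclase-associated protein 1	2D-WB	6-9	7.14	NA	55.5	NA	5.5	NA	17.1	NA	NA	NA	8.0	18092833	false
30	30	CAP1	Adenylyl cyclase-associated protein 1	MS	6-9	7.38	NA	54.8	NA	4.4	NA	11.2	NA	NA	NA	21.4	18092833	false
31	31	CAP1	Adenylyl cyclase-associated protein 1	2D-WB	6-9	7.66	NA	55.1	NA	7.7	NA	8.7	NA	NA	NA	3.7	18092833	false
32	32	GAPDH	Glyceraldehyde-3-phosphate dehydrogenase	MS	6-9	8.68	8.57	39.1	36.1	9.1	5.6	32.5	20.6	13.9	53.6	62.8	191046667	false
33	31	GAPDH	Glyceraldehyde-3-phosphate dehydrogenase	MS	6-9	8.78	NA	39.0	NA	7.7	NA	25.1	NA	NA	NA	626.3	191046667	false
34	34	GAPDH	Glyceraldehyde-3-phosphate dehydrogenase	2D-WB	6-9	8.88	NA	39.1	NA	4.7	NA	30.8	NA	NA	NA	55.5	191046667	false
35	35	GAPDH	Glyceraldehyde-3-phosphate dehydrogenase	2D-WB	6-9	9.01	NA	39.0	NA	3.1	NA	5.3	NA	NA	NA	13.0	191046667	false
36	36	GAPDH	Glyceraldehyde-3-phosphate dehydrogenase	MS	6-9	9.21	NA	38.8	NA	3.3	NA	9.5	NA	NA	NA	5.6	191046667	false
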
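assembly_id	lineage_class	kind	site	assembly_mbp	gc_percent	has_16s	completeness_pct	predicted_size_mbp	contamination_pct	quality	size_reproducible
AD-967-E21	Rokumicrobia	SAG	Finsch	1.52	66	1	30	5.1	<1	Low	1
AG-128-L10	Infratellusbacteria	SAG	CS	1.89	70	1	24	7.9	<1	Low	1
AG-138-D06	Rokumicrobia	SAG	SURF	0.29	67	1	6	4.9	0	Low	0
AG-657-A01	Rokumicrobia	SAG	OV-2	0.40	68	1	<1	NA	0	Low	1
AG-657-I10	Infratellusbacteria	SAG	OV-2	0.93	71	1	<1	NA	0	Low	1
AG-657-L06	Rokumicrobia	SAG	OV-2	1.03	65	1	<1	NA	0	Low	1
AG-159-B15	Rokumicrobia	SAG	OV-2	0.05	64	1	<1	NA	0	Low	1
AG-159-G23	Rokumicrobia	SAG	OV-2	0.40	64	0	5	8.1	0	Low	0
AG-159-L22	Rokumicrobia	SAG	OV-2	0.69	65	1	16	4.3	0	Low	1
AG-159-M09	Rokumicrobia	SAG	OV-2	0.93	65	1	4	22.2	0	Low	0
AG-159-N17	Infratellusbacteria	SAG	OV-2	0.41	67	1	<1	NA	0	Low	1
AG-159-P01	Rokumicrobia	SAG	OV-2	0.07	65	0	<1	NA	0	Low	1
AG-160-L13	Infratellusbacteria	SAG	OV-2	0.41	64	1	3	13.7	0	Low	1
AG-160-P19	Rokumicrobia	SAG	OV-2	1.38	64	1	27	5.1	<1	Low	1
AG-278-A09	Rokumicrobia	SAG	OV-2	0.24	65	1	4	6.1	0	Low	0
AG-278-B04	Rokumicrobia	SAG	OV-2	2.61	69	1	32	8.2	<1	Low	1
AG-278-C09	Rokumicrobia	SAG	OV-2	1.68	68	1	18	9.21	0	Low	0
AG-278-N11	Rokumicrobia	SAG	OV-2	1.15	67	1	15	7.8	0	Low	0
AG-278-N20	Rokumicrobia	SAG	OV-2	2.86	67	1	40	7.2	0	Low	1
OV-2_bin8	Infratellusbacteria	bin	OV-2	5.69	72	1	89	6.4	2	Medium	1
Rhizosphere_bin	Rokumicrobia	bin	PR	4.01	69	1	63	6.4	1	Low	1
OV-2_bin1	Unknown	bin	OV-2	11.84	62	0	100	11.8	332	NA	1
OV-2_bin2	Unknown	bin	OV-2	11.68	69	0	100	11.6	175	NA	0
OV-2_bin6	Unknown	bin	OV-2	6.06	69	0	73	8.3	59	NA	1
OV-2_bin9	Unknown	bin	OV-2	5.05	71	0	78	6.5	34	NA	1
OV-2_bin11	Unknown	bin	OV-2	4.68	68	0	98	4.8	153	NA	1
OV-2_bin43	Unknown	bin	OV-2	1.32	72	0	14	9.5	1	Low	0
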
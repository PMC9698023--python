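phylum	class	order	family	genus	median	sd	prevalence	p2_5	p10	p90	p97_5
Actinobacteria	Coriobacteriia	Coriobacteriales	Coriobacteriaceae	Collinsella	5.93	6.456	96.4	0.81	1.62	16.98	25.35
Actinobacteria	Coriobacteriia	Coriobacteriales	Eggerthellaceae	Slackia	0.15	0.178	55.6	0.04	0.06	0.51	0.66
Bacteroidetes	Bacteroidia	Bacteroidales	Bacteroidaceae	Bacteroides	8.34	9.421	100	0.45	1.3	25.74	32.25
Bacteroidetes	Bacteroidia	Bacteroidales	Prevotellaceae	Prevotella 9	23.17	17.55	80.5	0.11	1.02	46.51	56.69
Bacteroidetes	Bacteroidia	Bacteroidales	Tannerellaceae	Parabacteroides	0.51	1.038	80.5	0.08	0.14	1.57	3.71
Firmicutes	Clostridia	Clostridiales	Clostridiaceae	Clostridium sensu stricto 1	1.2	3.237	84	0.06	0.15	6.39	11.39
Firmicutes	Clostridia	Clostridiales	Lachnospiraceae	Ruminococcus gauvreauii	0.37	0.503	90.5	0.07	0.13	1.05	1.67
Firmicutes	Clostridia	Clostridiales	Lachnospiraceae	Ruminococcus gnavus	0.51	1.478	97	0.06	0.11	2.4	5.1
Firmicutes	Clostridia	Clostridiales	Lachnospiraceae	Ruminococcus torques	0.6	0.818	91.1	0.08	0.16	2.12	2.8
Firmicutes	Clostridia	Clostridiales	Lachnospiraceae	Blautia	5.44	5.65	100	1	1.84	13.88	20.96
Firmicutes	Clostridia	Clostridiales	Lachnospiraceae	Lachnoclostridium	1.13	1.103	98.2	0.2	0.4	3	4.28
Firmicutes	Clostridia	Clostridiales	Lachnospiraceae	Lachnospiraceae NK4A136	0.28	0.43	86.4	0.05	0.11	0.83	1.68
Firmicutes	Clostridia	Clostridiales	Lachnospiraceae	UnclassifiedLachnospiraceae	0.92	1.165	96.4	0.13	0.28	2.63	3.72
Firmicutes	Clostridia	Clostridiales	Lachnospiraceae	Lachnospiraceae UCG-009	0.18	0.223	72.2	0.05	0.07	0.57	0.94
Firmicutes	Clostridia	Clostridiales	Lachnospiraceae	Lachnospiraceae uncultured	0.8	0.888	93.5	0.11	0.21	2.04	3.22
Firmicutes	Clostridia	Clostridiales	Peptococcaceae	Peptococcus	0.57	1.37	65.1	0.09	0.13	2.64	4.62
Firmicutes	Clostridia	Clostridiales	Peptostreptococcaceae	Peptoclostridium	4.52	5.047	89.3	0.55	1.19	12.82	19.28
Firmicutes	Clostridia	Clostridiales	Ruminococcaceae	Butyricicoccus	0.17	0.28	68	0.04	0.07	0.45	0.92
Firmicutes	Clostridia	Clostridiales	Ruminococcaceae	Faecalibacterium	1.38	1.95	79.9	0.08	0.24	4.72	7.49
Firmicutes	Clostridia	Clostridiales	Ruminococcaceae	Negativibacillus	1.19	1.529	95.3	0.11	0.23	3.58	5.69
Firmicutes	Clostridia	Clostridiales	Ruminococcaceae	Oscillibacter	0.25	0.327	79.9	0.04	0.08	0.61	0.99
Firmicutes	Clostridia	Clostridiales	Ruminococcaceae	Ruminiclostridium 9	0.43	0.458	84.6	0.05	0.08	1.15	1.65
Firmicutes	Clostridia	Clostridiales	Ruminococcaceae	Ruminococcaceae UCG-014	0.61	3.432	74.6	0.06	0.12	3.07	9.41
Firmicutes	Clostridia	Clostridiales	Ruminococcaceae	Ruminococcaceae uncultured	0.15	0.255	60.4	0.03	0.05	0.48	0.95
Firmicutes	Erysipelotrichia	Erysipelotrichales	Erysipelotrichaceae	Catenibacterium	2.01	2.179	56.2	0.16	0.39	5.6	7.42
Firmicutes	Erysipelotrichia	Erysipelotrichales	Erysipelotrichaceae	Holdemanella	0.85	2.371	66.9	0.08	0.17	3.32	10.01
Firmicutes	Negativicutes	Selenomonadales	Veillonellaceae	Megamonas	1.81	5.355	75.7	0.1	0.15	8.37	19.25
Firmicutes	Negativicutes	Selenomonadales	Veillonellaceae	Megasphaera	5.21	7.796	58	0.15	0.4	16.67	28.39
Fusobacteria	Fusobacteriia	Fusobacteriales	Fusobacteriaceae	Fusobacterium	3.95	6.149	88.8	0.11	0.28	13.43	21.86
Proteobacteria	Gammaproteobacteria	Betaproteobacteriales	Burkholderiaceae	Sutterella	2.23	2.846	97	0.14	0.46	6.28	9.85
				Core Microbiome Total	82.59	6.775	NA	67.65	74.07	91.59	93.99
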
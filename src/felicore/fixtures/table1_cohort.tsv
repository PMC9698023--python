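age_class	n	age_months_mean	age_months_sd	fecal_score_mean	fecal_score_sd	bcs_mean	bcs_sd	female_pct	spayed_neutered_pct
junior	58	21.5	8.48	2.7	1.04	5.2	0.38	47	95
prime	59	58.7	15.28	2.7	0.95	5	0.61	61	86
mature	44	109.5	15.84	3.1	0.99	5.1	0.56	59	93
senior	6	141.3	4.32	3.2	0.5	5.6	0.55	50	83
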
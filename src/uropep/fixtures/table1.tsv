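# Cohort demographics transcribed from the source publication's clinical
# table (tidy form; one row per study phase x patient group). Ages as
# mean/min/max in years; sex as female/male counts. The discovery non-HCC
# group comprises 25 LC, 8 NASH w/o LC, 9 NAFLD and 9 healthy controls.
phase	group	n	age_mean	age_min	age_max	n_female	n_male
discovery	HCC	18	58	28	76	3	15
discovery	NONHCC	51	52	18	82	20	31
validation	HCC	39	67	38	87	9	30
validation	NONHCC	87	56	20	85	35	52
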
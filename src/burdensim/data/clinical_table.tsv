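section	field	misc_n	btnl8_n	iei_n
meta	cohort_size	154	9	6
demographics	sex_male	88	4	6
demographics	comorbidities	51	2	2
ancestry	AMR	45	2	1
ancestry	AFR	41	3	3
ancestry	EUR	40	3	1
ancestry	SAS	18	1	0
ancestry	EAS	5	0	1
ancestry	Unknown	5	0	0
sars_cov_2	pcr_positive	21	1	0
sars_cov_2	serology_positive	125	6	6
sars_cov_2	serology_unknown	13	2	0
symptoms	fever	154	9	6
symptoms	GI	122	9	6
symptoms	conjunctivitis	99	8	5
symptoms	rash	87	6	5
symptoms	systemic_shock	46	4	2
symptoms	cardiovascular	45	2	1
symptoms	lymphadenopathy	26	1	0
symptoms	inflamed_extremities	21	2	2
symptoms	respiratory	16	0	0
symptoms	mucositis	14	0	0
severity	ICU	98	5	4
severity	death	1	0	0
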
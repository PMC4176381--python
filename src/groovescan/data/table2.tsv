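ligand	K_Minv	K_err_Minv	Kd_uM	dG_kcal_mol	dG_err	dH_kcal_mol	dH_err	TdS_neg_kcal_mol	TdS_neg_err	flag
CGTGGGAA	2.2e7	1.4e7	0.06	-9.4	0.3	5.1	1.0	-14.5	0.7	fit
TGTGGGAA	2.0e6	0.5e6	0.50	-8.2	0.1	8.8	1.2	-17.0	1.0	fit
CGTGTGAC	5.9e5	1.0e5	1.72	-7.5	0.1	4.8	1.0	-12.3	1.0	fit
CGTAAGAA	NA	NA	>50	NA	NA	NA	NA	NA	NA	weak
TCATACCT	NBD	NBD	NBD	NBD	NBD	NBD	NBD	NBD	NBD	nbd
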
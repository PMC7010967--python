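metabolite_id	metabolite_name	causal_gene	n_associations	most_significant_tissue	q_value
M35439	glutarylcarnitine	GCDH	38	whole blood	1.88e-39
M01110	arachidonate (20:4n6)	FADS1	27	thyroid	1.09e-78
M32412	butyrylcarnitine	ACADS	26	lung	5.64e-202
M01110	arachidonate (20:4n6)	FADS2	26	esophagus gastresophageal junction	1.76e-48
M37058	succinylcarnitine	CRAT	23	cells transformed lymphocytes	5.78e-13
M00606	uridine	TYMP	20	cells transformed fibroblasts	1.36e-11
M35433	hydroxyisovaleroyl carnitine	MCCC1	16	skin sun exposed	1.29e-9
M01604	urate	SLC2A9	14	muscle skeletal	3.57e-34
M03141	betaine	BHMT	11	brain frontal cortex	3.21e-12
M32338	glycine	CPS1	10	brain putamen	3.15e-10
M32654	3-dehydrocarnitine	SLC22A5	10	skin not sun exposed	5.64e-14
M01123	inosine	NT5E	8	spleen	3.19e-9
M15500	carnitine	SLC16A9	8	esophagus mucosa	1.28e-44
M15140	kynurenine	SLC7A5	8	adipose visceral	1.58e-12
M22138	homocitrulline	SLC7A9	7	colon transverse	2.02e-4
M01110	arachidonate (20:4n6)	FADS3	6	liver	9.96e-55
M35159	cysteine-glutathione disulfide	GGT1	6	esophagus mucosa	1.88e-8
M35439	glutarylcarnitine	SLC7A6	6	spleen	4.24e-14
M35439	glutarylcarnitine	CPT2	5	colon sigmoid	8.48e-8
M01494	5-oxoproline	OPLAH	4	skin sun exposed	5.08e-98
M02137	biliverdin	UGT1A1	4	skin not sun exposed	1.16e-49
M32315	serine	PHGDH	3	colon sigmoid	2.73e-13
M33441	isobutyrylcarnitine	SLC22A1-2	3	skin not sun exposed	3.20e-5
M32654	3-dehydrocarnitine	SLC22A4	3	skin sun exposed	1.06e-17
M15500	carnitine	SLC22A4	3	artery tibial	2.01e-7
M15500	carnitine	SLC22A5	3	brain cerebellum	1.04e-3
M37097	tryptophan betaine	SLC22A5	3	brain putamen	2.35e-5
M18349	indolelactate	CCBL1	2	brain cortex	2.01e-4
M03127	hypoxanthine	GMPR	2	brain cerebellar hemisphere	2.28e-3
M22130	phenyllactate (PLA)	GOT2	2	brain frontal cortex	1.05e-8
M35631	1-palmitoylglycerophosphoethanolamine	LIPC	2	pancreas	3.96e-6
M03141	betaine	SLC6A12	2	lung	1.48e-3
M02132	citrulline	ALDH18A1	1	skin sun exposed	8.07e-3
M33937	alpha-hydroxyisovalerate	HAO2	1	adrenal gland	1.53e-6
M32315	serine	PSPH	1	esophagus mucosa	5.34e-4
M00054	tryptophan	SLC16A10	1	brain frontal cortex	6.71e-3
M01299	tyrosine	SLC16A10	1	brain frontal cortex	5.8e-4
M32412	butyrylcarnitine	SLC16A9	1	esophagus mucosa	1.85e-4
M32348	2-aminobutyrate	SLC1A4	1	muscle skeletal	1.96e-12
M37097	tryptophan betaine	SLC22A4	1	artery tibial	3.28e-7
M32379	scyllo-inositol	SLC5A11	1	brain hippocampus	4.74e-3
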
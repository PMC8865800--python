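patient_id	age	treatment	stage	pfi_days	crs	ca125_tn	ca125_pn	scrnaseq_tn	scrnaseq_pn	bulk_tn	bulk_pn	bulk_relapse
EOC1005	73	NACT	IVA	65	2	3776	343	Peritoneum	Tumor	NA	NA	NA
EOC136	64	NACT	IVA	520	2	2647	212	Mesentery	Omentum	NA	NA	NA
EOC153	78	NACT	IVA	393	2	1063	93	Omentum	Omentum	NA	NA	NA
EOC227	74	NACT	IVA	230	2	445	33	Omentum	Omentum	NA	NA	NA
EOC3	67	NACT	IVA	14	2	821	221	Peritoneum	Omentum	Peritoneum	Omentum	NA
EOC349	67	NACT	IVB	36	2	2155	67	Peritoneum	Omentum	NA	NA	NA
EOC372	68	NACT	IIIC	460	1	3180	334	Peritoneum	Peritoneum	Peritoneum	Peritoneum	NA
EOC443	54	NACT	IVA	177	3	2295	82	Omentum	Omentum	Omentum	Omentum	NA
EOC540	62	NACT	IIIC	126	2	155	7	Omentum	Omentum	NA	NA	NA
EOC733	72	NACT	IVA	83	1	22079	3579	Peritoneum	Omentum	NA	NA	NA
EOC87	62	NACT	IIIC	30	1	998	346	Peritoneum	Omentum	Omentum	Omentum	NA
EOC1129	75	NACT	IIIC	210	NA	3493	212	NA	NA	Omentum	Mesentery	NA
EOC160	68	PDS	IVB	648	NA	145	NA	NA	NA	Omentum	NA	Mesentery
EOC183	68	NACT	IIIC	203	2	411	15	NA	NA	Omentum	Omentum	NA
EOC218	71	NACT	IIIC	974	2	2633	38	NA	NA	Omentum	Omentum	NA
EOC26	72	NACT	IIIC	0	2	553	55	NA	NA	Omentum	Omentum	Ascites
EOC376	67	NACT	IIIC	280	1	615	20	NA	NA	Omentum	Omentum	NA
EOC423	81	NACT	IIIC	721	2	854	20	NA	NA	Omentum	Ovary	NA
EOC568	57	NACT	IVA	210	3	192	70	NA	NA	Mesentery	Omentum	NA
EOC587	71	NACT	IVB	27	3	149	22	NA	NA	Peritoneum	Tumor	NA
EOC649	77	NACT	IVB	511	2	588	22	NA	NA	Peritoneum	Omentum	NA
EOC677	68	NACT	IIIC	81	2	1593	11	NA	NA	Peritoneum	Peritoneum	Ascites
EOC883	74	NACT	IIIC	91	NA	1515	NA	NA	NA	Adnexa	Ascites	NA
EOC891	71	NACT	IIIC	183	NA	687	NA	NA	NA	Omentum	NA	Ascites
EOC933	74	NACT	IIIC	632	3	296	13	NA	NA	Peritoneum	Mesentery	NA
EOC868	62	NACT	IIIC	285	2	1565	36	NA	NA	Peritoneum	Omentum	Peritoneum
EOC1133	66	NACT	IVB	661	2	1156	22	NA	NA	Peritoneum	Omentum	NA
EOC167	75	NACT	IIIC	19	NA	5614	NA	NA	NA	Omentum	NA	Ascites
EOC295	66	NACT	IIIC	221	2	320	74	NA	NA	Peritoneum	NA	Ascites
EOC752	64	NACT	IIIC	174	2	2341	58	NA	NA	Peritoneum	NA	Ascites
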